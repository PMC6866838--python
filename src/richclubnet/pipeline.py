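"""End-to-end cohort analysis: connectomes -> metrics -> rich club -> inference.

This is the library layer beneath the command-line interface.  It takes a
multi-subject streamline table (or prebuilt connectomes) plus subject
metadata and produces the full set of result tables for a case-control
rich-club study: global graph measures with group tests, rich-club node
selection and curves, connection-class strengths with permutation-FWE group
tests and percent reductions, a fibre-length median-split table, SVD-marker
correlations, covariate-adjusted regressions of cognition on rich-club
strength, and Sobel mediation.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, richclub, stats
from .connectome import Connectome, build_connectome, threshold_edges

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisResults", "analyze_cohort", "write_results"]


@dataclass
class AnalysisConfig:
    """Parameters of an analysis run; defaults mirror the primary analysis.

    scale is the seeding-density correction applied when building weights;
    tau the weight threshold; n_rich the rich-club size; n_null the number of
    degree-preserving random networks for normalization; n_perm the number of
    label permutations for family-wise-error control.  Subject subsample
    sizes bound the cost of the per-subject null-model computations.
    """

    n_nodes: int = 90
    scale: float = 10.0
    tau: float = 1.0
    n_rich: int = 8
    selection: str = "group_mean"  # group_mean | group_average_network | individual
    prevalence: float = 0.30
    n_null: int = 100
    n_perm: int = 10000
    permutation_mode: str = "max-stat"
    seed: int = 0
    covariates: tuple[str, ...] = ("age", "sex", "iq_or_education")
    norm_eff_subjects: int = 6     # per group, for normalized efficiencies
    norm_eff_null: int = 30
    phi_subjects: int = 10         # per group, for per-subject phi_norm
    phi_null: int = 20

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class AnalysisResults:
    tables: dict[str, pd.DataFrame]
    summary: dict


def _build_all(
    table: pd.DataFrame, cfg: AnalysisConfig
) -> dict[str, Connectome]:
    out = {}
    for sid, sub in table.groupby("subject_id", sort=True):
        c = build_connectome(sub, n_nodes=cfg.n_nodes, scale=cfg.scale)
        out[str(sid)] = threshold_edges(c, cfg.tau)
    return out


def _group_mean_connectome(
    connectomes: list[Connectome], prevalence: float
) -> Connectome:
    """Mean-weight network restricted to edges present in >= prevalence of subjects."""
    presence = np.mean([(c.weights > 0) for c in connectomes], axis=0)
    w = np.mean([c.weights for c in connectomes], axis=0)
    ml = np.mean([c.mean_length for c in connectomes], axis=0)
    keep = presence >= prevalence
    w = np.where(keep, w, 0.0)
    ml = np.where(keep, ml, 0.0)
    np.fill_diagonal(w, 0.0)
    np.fill_diagonal(ml, 0.0)
    return Connectome(w, ml, list(connectomes[0].labels))


def _subject_phi_norm(
    c: Connectome, n_rich: int, n_null: int, seed
) -> float:
    """phi_norm at this subject's hub regime (degree > (n_rich+1)-th largest)."""
    deg = np.sort(metrics.degree(c))[::-1]
    if len(deg) <= n_rich or deg[n_rich] < 1:
        return float("nan")
    k = int(deg[n_rich])
    curve = richclub.normalized_rich_club(c, np.array([k]), n_null=n_null, seed=seed)
    return float(curve.phi_norm[0])


def analyze_cohort(
    streamline_table: pd.DataFrame,
    metadata: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    connectomes: dict[str, Connectome] | None = None,
) -> AnalysisResults:
    """Run the full case-control analysis.  See the module docstring."""
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(cfg.seed)
    if connectomes is None:
        connectomes = _build_all(streamline_table, cfg)
    meta = metadata.set_index("subject_id", drop=False)
    ids = [sid for sid in meta["subject_id"] if sid in connectomes]
    if not ids:
        raise ValueError("no overlap between metadata subjects and connectomes")
    meta = meta.loc[ids]
    groups = meta["group"].to_numpy()
    is_control = groups == "control"
    conns = [connectomes[s] for s in ids]

    # ---- global graph measures -------------------------------------------
    glob = pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "density": [metrics.density(c) for c in conns],
            "total_strength": [metrics.total_strength(c) for c in conns],
            "global_efficiency": [metrics.global_efficiency(c) for c in conns],
            "local_efficiency": [metrics.local_efficiency(c) for c in conns],
            "mean_degree": [metrics.degree(c).mean() for c in conns],
        }
    )

    # normalized efficiencies on a per-group subject subsample
    norm_rows = []
    for gname, gmask in (("control", is_control), ("svd", ~is_control)):
        idx = np.flatnonzero(gmask)[: cfg.norm_eff_subjects]
        for s in idx:
            ng, nl = metrics.normalized_efficiencies(
                conns[s], n_null=cfg.norm_eff_null, seed=rng
            )
            norm_rows.append(
                {
                    "subject_id": ids[s],
                    "group": gname,
                    "norm_global_efficiency": ng,
                    "norm_local_efficiency": nl,
                }
            )
    norm_eff = pd.DataFrame(norm_rows)

    # ---- rich-club node selection ----------------------------------------
    if cfg.selection == "group_mean":
        rich_set = richclub.select_rich_nodes_group_mean(conns, cfg.n_rich)
    elif cfg.selection == "group_average_network":
        rich_set = richclub.select_rich_nodes_group_average_network(
            conns, cfg.prevalence, cfg.n_rich
        )
    elif cfg.selection == "individual":
        rich_set = None
    else:
        raise ValueError(f"unknown selection scheme {cfg.selection!r}")

    # ---- per-subject class strengths -------------------------------------
    cs_rows = []
    for s, c in zip(range(len(ids)), conns):
        rset = (
            richclub.select_rich_nodes_individual(c, cfg.n_rich / c.n)
            if rich_set is None
            else rich_set
        )
        cm = richclub.classify_edges(c, rset)
        cs = richclub.class_strengths(c, cm)
        cs_rows.append(
            {
                "subject_id": ids[s],
                "group": groups[s],
                "rich": cs.strengths["rich"],
                "feeder": cs.strengths["feeder"],
                "peripheral": cs.strengths["peripheral"],
                "ratio_rich_feeder": cs.ratio_rich_feeder,
                "ratio_rich_peripheral": cs.ratio_rich_peripheral,
                "total_strength": metrics.total_strength(c),
            }
        )
    class_table = pd.DataFrame(cs_rows)

    # ---- group tests with permutation FWE --------------------------------
    def _welch_row(name: str, values: np.ndarray) -> dict:
        r = stats.welch_t(values[is_control], values[~is_control])
        return {
            "measure": name,
            "mean_control": r.mean_x,
            "mean_svd": r.mean_y,
            "percent_reduction": r.percent_reduction,
            "t": r.statistic,
            "df": r.df,
            "p_raw": r.p_raw,
        }

    rows = [
        _welch_row(m, glob[m].to_numpy())
        for m in ("density", "total_strength", "global_efficiency", "local_efficiency")
    ]
    class_measures = ["rich", "feeder", "peripheral"]
    for m in class_measures + ["ratio_rich_feeder", "ratio_rich_peripheral"]:
        rows.append(_welch_row(m, class_table[m].to_numpy()))
    group_tests = pd.DataFrame(rows)

    perm = stats.permutation_fwe(
        class_table[class_measures].to_numpy(),
        groups,
        n_perm=cfg.n_perm,
        seed=rng,
        mode=cfg.permutation_mode,
    )
    fwe = dict(zip(class_measures, perm.p_fwe))
    group_tests["p_fwe"] = [fwe.get(m, np.nan) for m in group_tests["measure"]]

    # covariate-adjusted group differences on rich strength
    adj_rows = []
    for covname, cov in (
        ("total_network_strength", class_table[["total_strength"]]),
        ("brain_volume", meta[["brain_volume_ml"]].reset_index(drop=True)),
    ):
        try:
            r = stats.adjusted_group_difference(
                class_table["rich"].to_numpy(), groups, cov
            )
            adj_rows.append(
                {
                    "outcome": "rich",
                    "adjusted_for": covname,
                    "t": r.statistic,
                    "df": r.df,
                    "p": r.p_raw,
                }
            )
        except ValueError as exc:  # pragma: no cover - degenerate cohorts
            logger.warning("adjusted analysis %s failed: %s", covname, exc)
    adjusted = pd.DataFrame(
        adj_rows, columns=["outcome", "adjusted_for", "t", "df", "p"]
    )

    # ---- rich-club curves on group-representative networks ---------------
    curve_rows = []
    for gname, gmask in (("control", is_control), ("svd", ~is_control)):
        rep = _group_mean_connectome(
            [c for c, m in zip(conns, gmask) if m], cfg.prevalence
        )
        curve = richclub.normalized_rich_club(rep, n_null=cfg.n_null, seed=rng)
        for k, phi, phi_rand, phi_norm in zip(
            curve.k, curve.phi, curve.phi_rand, curve.phi_norm
        ):
            curve_rows.append(
                {
                    "group": gname,
                    "k": int(k),
                    "phi": phi,
                    "phi_rand": phi_rand,
                    "phi_norm": phi_norm,
                    "n_null": curve.n_null,
                }
            )
    curves = pd.DataFrame(curve_rows)

    # per-subject phi_norm at the hub regime, on a subsample
    phi_rows = []
    for gname, gmask in (("control", is_control), ("svd", ~is_control)):
        idx = np.flatnonzero(gmask)[: cfg.phi_subjects]
        for s in idx:
            phi_rows.append(
                {
                    "subject_id": ids[s],
                    "group": gname,
                    "phi_norm": _subject_phi_norm(
                        conns[s], cfg.n_rich, cfg.phi_null, rng
                    ),
                }
            )
    phi_subjects = pd.DataFrame(phi_rows)
    phi_test = None
    pc = phi_subjects.query("group == 'control'")["phi_norm"].dropna()
    ps = phi_subjects.query("group == 'svd'")["phi_norm"].dropna()
    if len(pc) >= 2 and len(ps) >= 2:
        phi_test = stats.welch_t(pc, ps)

    # ---- fibre-length median split (control group) -----------------------
    split_acc: dict[tuple[str, str], list[dict]] = {}
    for c, m in zip(conns, is_control):
        if not m:
            continue
        rset = (
            richclub.select_rich_nodes_individual(c, cfg.n_rich / c.n)
            if rich_set is None
            else rich_set
        )
        split = richclub.length_median_split(c, richclub.classify_edges(c, rset))
        for cls, subsets in split.items():
            for sub, summ in subsets.items():
                split_acc.setdefault((cls, sub), []).append(summ)
    split_rows = []
    for (cls, sub), summaries in split_acc.items():
        split_rows.append(
            {
                "class": cls,
                "subset": sub,
                "mean_length_mm": float(
                    np.nanmean([s["mean_length"] for s in summaries])
                ),
                "mean_strength": float(np.mean([s["strength"] for s in summaries])),
                "mean_n_edges": float(np.mean([s["n_edges"] for s in summaries])),
            }
        )
    length_split = pd.DataFrame(split_rows)

    # ---- SVD-marker correlations (patients, strength-corrected) ----------
    svd_class = class_table[~is_control].reset_index(drop=True)
    svd_meta = meta[~is_control].reset_index(drop=True)
    markers = None
    if (~is_control).sum() >= 3:
        markers = stats.correlate_markers(
            svd_class[["rich", "feeder", "peripheral"]],
            svd_meta[["wmh_ml", "lacune_count"]],
            svd_class["total_strength"],
        )

    # ---- cognition: regression and mediation (patients) ------------------
    reg_rows, med_rows = [], []
    covs = svd_meta[list(cfg.covariates)] if cfg.covariates else None
    have_cog = {"processing_speed_z", "executive_z"} <= set(svd_meta.columns)
    if have_cog and (~is_control).sum() > len(cfg.covariates) + 4:
        for outcome in ("processing_speed_z", "executive_z"):
            reg = stats.standardized_regression(
                svd_meta[outcome].to_numpy(), svd_class["rich"].to_numpy(), covs
            )
            reg_rows.append(
                {
                    "outcome": outcome,
                    "predictor": "rich_strength",
                    "beta": float(reg.beta["predictor"]),
                    "p": float(reg.pvalues["predictor"]),
                    "r_squared": reg.r_squared,
                    "max_vif": float(reg.vif.max()),
                    "multicollinearity": reg.multicollinearity,
                }
            )
        for xname, xvals in (
            ("wmh_ml", stats.log_transform(svd_meta["wmh_ml"])),
            ("lacune_count", stats.log_transform(svd_meta["lacune_count"])),
        ):
            med = stats.sobel_mediation(
                xvals,
                svd_class["rich"].to_numpy(),
                svd_meta["processing_speed_z"].to_numpy(),
                covs,
            )
            med_rows.append(
                {
                    "exposure": xname,
                    "mediator": "rich_strength",
                    "outcome": "processing_speed_z",
                    "a": med.a,
                    "se_a": med.se_a,
                    "b": med.b,
                    "se_b": med.se_b,
                    "indirect": med.indirect,
                    "sobel_z": med.sobel_z,
                    "p": med.p_two_sided,
                }
            )
    regression = pd.DataFrame(
        reg_rows,
        columns=[
            "outcome", "predictor", "beta", "p", "r_squared", "max_vif",
            "multicollinearity",
        ],
    )
    mediation = pd.DataFrame(
        med_rows,
        columns=[
            "exposure", "mediator", "outcome", "a", "se_a", "b", "se_b",
            "indirect", "sobel_z", "p",
        ],
    )

    labels = conns[0].labels
    summary = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_control": int(is_control.sum()),
        "n_svd": int((~is_control).sum()),
        "rich_set_labels": (
            [labels[i] for i in rich_set] if rich_set is not None else "individual"
        ),
        "selection_scheme": cfg.selection,
        "permutation_mode": cfg.permutation_mode,
        "phi_norm_group_test": (
            {
                "t": phi_test.statistic,
                "df": phi_test.df,
                "p": phi_test.p_raw,
                "mean_control": phi_test.mean_x,
                "mean_svd": phi_test.mean_y,
            }
            if phi_test is not None
            else None
        ),
        "design_flags": {
            "edge_traversal_length": "1/weight",
            "threshold_rule": "weights < tau removed, == tau kept",
            "degree_threshold_rule": "strict (degree > k)",
            "median_split_ties": "to short",
            "rich_set_tie_break": "strength then lower index",
            "permutation_p": "add-one (Phipson-Smyth)",
        },
    }
    tables = {
        "global_metrics": glob,
        "normalized_efficiency": norm_eff,
        "class_strengths": class_table,
        "group_tests": group_tests,
        "adjusted_tests": adjusted,
        "rich_club_curves": curves,
        "phi_norm_subjects": phi_subjects,
        "length_split": length_split,
        "regression": regression,
        "mediation": mediation,
    }
    if markers is not None:
        tables["marker_correlations"] = markers
    return AnalysisResults(tables=tables, summary=summary)


def write_results(results: AnalysisResults, outdir, force: bool = False) -> None:
    """Write all result tables as TSV plus a machine-readable summary.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in results.tables.items():
        path = outdir / f"{name}.tsv"
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
    spath = outdir / "summary.yaml"
    if spath.exists() and not force:
        raise FileExistsError(f"{spath} exists; pass force=True to overwrite")
    with open(spath, "w") as fh:
        yaml.safe_dump(results.summary, fh, sort_keys=False)
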