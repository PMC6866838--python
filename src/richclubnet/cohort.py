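"""Synthetic small-vessel-disease cohort generator.

Generates streamline endpoint tables plus subject metadata whose networks
carry the statistical structure of a case-control structural-connectome
study of cerebral small vessel disease (SVD): a planted rich club of
interconnected high-degree hubs joined by physically long connections,
distance-dependent connectivity, right-skewed degree distributions,
class-specific lesioning concentrated on rich-club edges and coupled to
white-matter-hyperintensity (WMH) load, and cognitive scores with a mediated
WMH -> rich-club-strength -> processing-speed pathway.

The model deliberately has no anatomical realism: nodes are points in a
bilaterally mirrored ellipsoid (mm), streamline counts are Poisson, and
lengths are positive-truncated normal around the inter-node Euclidean
distance.  All randomness flows from one master seed through per-subject
spawned seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import STREAMLINE_COLUMNS
from .richclub import RICH, pair_classes

__all__ = [
    "TemplateNetwork",
    "CohortConfig",
    "Cohort",
    "generate_template",
    "sample_subject_streamlines",
    "apply_svd_lesion",
    "generate_cognition",
    "generate_cohort",
    "write_cohort",
    "read_metadata",
]

# Geometry and connectivity constants (mm and dimensionless).  Chosen once to
# emulate an AAL-style 90-region network: ~0.2 density, mean fibre lengths
# ordered rich > feeder > peripheral, hubs spread over long distances.
ELLIPSOID_SEMI_AXES = (60.0, 80.0, 55.0)   # left-right, ant-post, inf-sup
PROB_DECAY_MM = 45.0                       # connection probability decay scale
FEEDER_DECAY_MM = 70.0                     # hubs connect over longer ranges
BASE_PROB = 0.9                            # probability prefactor at distance 0
FEEDER_PROB_BOOST = 1.2                    # hub bonus on hub-to-nonhub pairs
HUB_HUB_PROB_BOOST = 30.0                  # hub bonus on hub-hub pairs
PROB_CAP = 0.95
# Expected built edge weight (at the recommended analysis scale) per class,
# with a mild decay in fibre length: w ~ W_CLASS * (LENGTH_REF / d) ** LENGTH_EXP.
W_RICH, W_FEEDER, W_PERIPHERAL = 5.0, 3.5, 3.0
LENGTH_REF_MM = 60.0
LENGTH_EXP = 0.3
LENGTH_SD_FRACTION = 0.10                  # streamline length sd = 10% of distance
NOISE_EDGE_PROB = 0.03                     # spurious low-count connections
NOISE_COUNT_MEAN = 1.5
SEVERITY_CAP = 2.5                         # cap on per-class lesion severity


@dataclass
class TemplateNetwork:
    """Expected structure all subjects are sampled from."""

    node_positions: np.ndarray      # (n, 3) mm
    hub_set: np.ndarray             # indices of planted hubs
    base_weight: np.ndarray         # expected built edge weight (dimensionless)
    base_prob: np.ndarray           # connection probability per pair
    count_mean: np.ndarray          # expected streamline count given connection
    distances: np.ndarray           # pairwise Euclidean distances (mm)
    noise_prob: float = NOISE_EDGE_PROB
    scale_hint: float = 10.0        # analysis scale the weights are calibrated to

    @property
    def n_nodes(self) -> int:
        return self.node_positions.shape[0]

    def expected_degree(self) -> np.ndarray:
        return self.base_prob.sum(axis=0)


@dataclass
class CohortConfig:
    """Study-condition parameters for a two-group synthetic cohort.

    Defaults mirror the discovery-style dataset: 50 controls vs 115 SVD
    patients on a 90-node parcellation with an 8-node rich club, lesion
    retention factors (0.63, 0.79, 0.79) producing 37.0% / 20.7% / 20.7%
    expected reductions in rich / feeder / peripheral connection strength,
    WMH volumes lognormal with mean 3.1 / SD 2.6 mL in patients (0.84 / 1.2
    in controls), lacune counts Poisson, and processing-speed scores driven
    by rich-club strength (beta 0.28) and lacunes (beta -0.33).
    """

    n_control: int = 50
    n_svd: int = 115
    n_nodes: int = 90
    n_hubs: int = 8
    lesion_factors: tuple[float, float, float] = (0.63, 0.79, 0.79)
    wmh_lognormal_params: dict = field(
        default_factory=lambda: {
            "control": {"mean": 0.84, "sd": 1.2},
            "svd": {"mean": 3.1, "sd": 2.6},
        }
    )
    lacune_poisson_mean: dict = field(
        default_factory=lambda: {"control": 0.45, "svd": 1.38}
    )
    cognition_coeffs: tuple[float, float, float] = (0.28, -0.33, 0.70)
    executive_coeffs: tuple[float, float, float] = (0.20, -0.27, 0.85)
    subject_noise_sd: float = 0.6
    lesion_jitter_sd: float = 0.55
    scale: float = 10.0     # recommended build scale (seeds-per-mm correction)
    tau: float = 1.0        # recommended edge threshold
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_svd", "n_nodes", "n_hubs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_hubs >= self.n_nodes:
            raise ValueError("n_hubs must be smaller than n_nodes")
        self.lesion_factors = tuple(float(f) for f in self.lesion_factors)
        if any(not 0 < f <= 1 for f in self.lesion_factors):
            raise ValueError("lesion_factors must lie in (0, 1]")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be non-negative")
        if self.lesion_jitter_sd < 0:
            raise ValueError("lesion_jitter_sd must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lesion_factors"] = list(self.lesion_factors)
        d["cognition_coeffs"] = list(self.cognition_coeffs)
        d["executive_coeffs"] = list(self.executive_coeffs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("lesion_factors", "cognition_coeffs", "executive_coeffs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class Cohort:
    template: TemplateNetwork
    tables: dict[str, pd.DataFrame]       # subject_id -> streamline table
    subjects: pd.DataFrame                # one row per subject
    config: CohortConfig

    def combined_table(self) -> pd.DataFrame:
        return pd.concat(
            [self.tables[s] for s in self.subjects["subject_id"]],
            ignore_index=True,
        )


def _hub_positions(n_hubs: int) -> np.ndarray:
    """Deep, near-midline hub coordinates in two anterior/posterior groups.

    Hubs sit at small lateral offsets but large anterior-posterior spread,
    so hub-hub connections are physically long, as rich-club edges are.
    """
    a, b, c = ELLIPSOID_SEMI_AXES
    if n_hubs < 4:
        # too few hubs for mirrored pairs: midline nodes spread front-to-back
        ys = np.linspace(-0.8, 0.8, n_hubs) * b
        return np.column_stack([np.zeros(n_hubs), ys, np.full(n_hubs, 0.2 * c)])
    pairs = n_hubs // 2
    slots = []
    for m in range(pairs):
        y = (0.8 if m % 2 == 0 else -0.8) * b          # alternate ant/post
        z = (0.25 if (m // 2) % 2 == 0 else -0.15) * c
        x = 0.2 * a * (1.0 + 0.15 * (m // 4))
        slots.append(((x, y, z), (-x, y, z)))
    coords = [p for pair in slots for p in pair]
    if n_hubs % 2 == 1:
        coords.append((0.0, 0.0, 0.35 * c))
    return np.array(coords[:n_hubs])


def generate_template(
    n_nodes: int = 90, n_hubs: int = 8, seed: int = 0
) -> TemplateNetwork:
    """Generate the expected network all subjects are drawn from.

    Non-hub nodes are sampled uniformly in a bilaterally mirrored ellipsoid;
    hubs occupy indices 0..n_hubs-1 at deep, widely separated positions.
    Connection probability decays exponentially with distance and is boosted
    on hub-involving pairs so the planted hubs occupy the top-n_hubs expected
    degree ranks; hub-hub expected weights are the strongest in the network.
    """
    if n_nodes <= 0 or n_hubs <= 0:
        raise ValueError("n_nodes and n_hubs must be positive")
    if n_hubs >= n_nodes:
        raise ValueError("n_hubs must be smaller than n_nodes")
    rng = np.random.default_rng(seed)
    a, b, c = ELLIPSOID_SEMI_AXES

    hubs = _hub_positions(n_hubs)
    n_other = n_nodes - n_hubs
    n_pairs, n_mid = divmod(n_other, 2)
    halves = []
    while len(halves) < n_pairs:
        cand = rng.uniform([-1, -1, -1], [1, 1, 1], size=(4 * n_pairs, 3))
        cand = cand[(cand**2).sum(axis=1) <= 1.0]
        cand = cand[cand[:, 0] > 0.05]
        halves.extend(cand.tolist())
    halves = np.array(halves[:n_pairs]) * np.array([a, b, c])
    mirrored = halves * np.array([-1.0, 1.0, 1.0])
    others = np.empty((n_other, 3))
    others[0 : 2 * n_pairs : 2] = halves
    others[1 : 2 * n_pairs : 2] = mirrored
    if n_mid:
        others[-1] = (0.0, rng.uniform(-0.5, 0.5) * b, rng.uniform(-0.5, 0.5) * c)
    positions = np.vstack([hubs, others])
    hub_set = np.arange(n_hubs)

    diff = positions[:, None, :] - positions[None, :, :]
    distances = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(distances, 0.0)

    is_hub = np.zeros(n_nodes, dtype=bool)
    is_hub[hub_set] = True
    hub_ends = is_hub[:, None].astype(int) + is_hub[None, :].astype(int)

    prob = BASE_PROB * np.exp(-distances / PROB_DECAY_MM)
    feeder_prob = BASE_PROB * FEEDER_PROB_BOOST * np.exp(-distances / FEEDER_DECAY_MM)
    prob = np.where(hub_ends == 1, feeder_prob, prob)
    prob = np.where(hub_ends == 2, prob * HUB_HUB_PROB_BOOST, prob)
    prob = np.clip(prob, 0.0, PROB_CAP)
    np.fill_diagonal(prob, 0.0)

    w_class = np.where(
        hub_ends == 2, W_RICH, np.where(hub_ends == 1, W_FEEDER, W_PERIPHERAL)
    )
    scale_hint = 10.0
    safe_d = np.maximum(distances, 1e-9)
    expected_weight = w_class * (LENGTH_REF_MM / safe_d) ** LENGTH_EXP
    count_mean = expected_weight * safe_d / scale_hint
    np.fill_diagonal(count_mean, 0.0)
    base_weight = expected_weight * prob  # unconditional expectation
    np.fill_diagonal(base_weight, 0.0)

    template = TemplateNetwork(
        node_positions=positions,
        hub_set=hub_set,
        base_weight=base_weight,
        base_prob=prob,
        count_mean=count_mean,
        distances=distances,
        scale_hint=scale_hint,
    )
    ed = template.expected_degree()
    if set(np.argsort(ed)[-n_hubs:]) != set(hub_set.tolist()):
        raise RuntimeError("planted hubs do not dominate expected degree")
    hub_d = distances[np.ix_(hub_set, hub_set)][np.triu_indices(n_hubs, 1)]
    non = np.flatnonzero(~is_hub)
    non_d = distances[np.ix_(non, non)][np.triu_indices(len(non), 1)]
    if not hub_d.mean() > non_d.mean():
        raise RuntimeError("hub pairs are not more distant than non-hub pairs")
    return template


def _positive_truncated_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    """Normal draws redrawn until positive (sd is ~10% of the mean here)."""
    out = rng.normal(mean, sd)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd[bad])
        bad = out <= 0
    return out


def sample_subject_streamlines(
    template: TemplateNetwork,
    noise_sd: float = 0.6,
    seed: int | np.random.Generator = 0,
    subject_id: str = "S000",
) -> pd.DataFrame:
    """Sample one subject's streamline table from the template.

    Each pair is connected with its template probability; realized edges get
    a Poisson streamline count with mean ``count_mean`` times an i.i.d.
    per-edge lognormal factor (mean 1, sd ``noise_sd``) drawn for this
    subject.  Spurious "noise" connections with very low counts appear on
    unconnected pairs with probability ``template.noise_prob`` (these fall
    below the recommended weight threshold).  Streamline lengths are
    positive-truncated normal around the inter-node distance.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = template.n_nodes
    iu = np.triu_indices(n, 1)
    prob = template.base_prob[iu]
    cmean = template.count_mean[iu]
    dist = template.distances[iu]

    connected = rng.random(len(prob)) < prob
    if noise_sd > 0:
        sigma = np.sqrt(np.log1p(noise_sd**2))
        factors = rng.lognormal(-sigma**2 / 2.0, sigma, size=len(prob))
    else:
        factors = np.ones(len(prob))
    counts = np.where(
        connected, rng.poisson(cmean * factors), 0
    )
    spurious = (~connected) & (rng.random(len(prob)) < template.noise_prob)
    counts = np.where(spurious, 1 + rng.poisson(NOISE_COUNT_MEAN - 1.0, len(prob)), counts)

    keep = counts > 0
    edge_i = iu[0][keep]
    edge_j = iu[1][keep]
    edge_counts = counts[keep]
    edge_dist = dist[keep]
    mean_rep = np.repeat(edge_dist, edge_counts)
    lengths = _positive_truncated_normal(rng, mean_rep, LENGTH_SD_FRACTION * mean_rep)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "node_i": np.repeat(edge_i + 1, edge_counts),
            "node_j": np.repeat(edge_j + 1, edge_counts),
            "length_mm": lengths,
        },
        columns=list(STREAMLINE_COLUMNS),
    )


def apply_svd_lesion(
    table: pd.DataFrame,
    classes: np.ndarray,
    lesion_factors: tuple[float, float, float],
    severity=1.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Thin streamlines per connection class to emulate SVD lesioning.

    ``classes`` is the (n, n) pair-class matrix (see ``pair_classes``).  Each
    streamline of class c is retained independently with probability
    ``clip(1 - (1 - f_c) * severity_c, 0, 1)``, so the expected retained
    weight fraction equals ``f_c`` at severity 1 and decreases with WMH
    severity, inducing the negative WMH/rich-strength correlation within
    patients.  ``severity`` is a scalar, or a per-class (rich, feeder,
    peripheral) triple when lesion topography differs between classes.
    """
    f_rich, f_feeder, f_peripheral = lesion_factors
    if any(not 0 <= f <= 1 for f in (f_rich, f_feeder, f_peripheral)):
        raise ValueError("lesion factors must lie in [0, 1]")
    sev = np.broadcast_to(np.asarray(severity, dtype=float), (3,))
    if np.any(sev < 0):
        raise ValueError("severity must be non-negative")
    if tuple(lesion_factors) == (1.0, 1.0, 1.0) or np.all(sev == 0):
        return table.copy()
    rng = np.random.default_rng(seed)
    i = np.asarray(table["node_i"], dtype=int) - 1
    j = np.asarray(table["node_j"], dtype=int) - 1
    codes = classes[i, j]
    if np.any(codes == 0):
        raise ValueError("streamline with unknown edge class (self-pair?)")
    loss = (1.0 - np.array([np.nan, f_rich, f_feeder, f_peripheral])) * np.concatenate(
        [[np.nan], sev]
    )
    retention = np.clip(1.0 - loss[codes], 0.0, 1.0)
    keep = rng.random(len(table)) < retention
    return table[keep].reset_index(drop=True)


def generate_cognition(
    rich_strength_z,
    lacunes,
    coeffs: tuple[float, float, float],
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Linear cognitive scores: beta_rc * rich_z + beta_lac * z(log1p(lacunes)) + noise."""
    beta_rc, beta_lac, noise_sd = coeffs
    for v in (beta_rc, beta_lac, noise_sd):
        if not np.isfinite(v):
            raise ValueError("cognition coefficients must be finite")
    rng = np.random.default_rng(seed)
    rz = np.asarray(rich_strength_z, dtype=float)
    lac = np.log1p(np.asarray(lacunes, dtype=float))
    sd = lac.std(ddof=0)
    lac_z = (lac - lac.mean()) / sd if sd > 0 else np.zeros_like(lac)
    noise = rng.normal(0.0, noise_sd, size=len(rz)) if noise_sd > 0 else 0.0
    return beta_rc * rz + beta_lac * lac_z + noise


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _latent_rich_strength(
    table: pd.DataFrame, classes: np.ndarray, scale: float
) -> float:
    """Rich-class connection strength straight from the streamline table."""
    i = np.asarray(table["node_i"], dtype=int) - 1
    j = np.asarray(table["node_j"], dtype=int) - 1
    sel = classes[i, j] == RICH
    return float(scale * (1.0 / np.asarray(table["length_mm"], dtype=float)[sel]).sum())


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full two-group cohort (streamline tables + metadata).

    WMH severity is log1p(WMH) normalized to mean 1 over the SVD group, so
    the expected per-class strength reduction equals the configured lesion
    factors exactly.  Controls are left unlesioned.  Cognitive scores use
    the subject's within-group z-scored (unthresholded) rich-club strength,
    so the configured mediation pathway WMH -> rich strength -> speed holds.
    """
    cfg = config
    master = np.random.SeedSequence(cfg.seed)
    n_total = cfg.n_control + cfg.n_svd
    seeds = master.spawn(n_total + 2)
    template = generate_template(cfg.n_nodes, cfg.n_hubs, seed=seeds[0])
    classes = pair_classes(cfg.n_nodes, template.hub_set)
    meta_rng = np.random.default_rng(seeds[1])

    groups = ["control"] * cfg.n_control + ["svd"] * cfg.n_svd
    ids = [f"C{k + 1:03d}" for k in range(cfg.n_control)] + [
        f"P{k + 1:03d}" for k in range(cfg.n_svd)
    ]

    wmh = np.empty(n_total)
    lacunes = np.empty(n_total, dtype=int)
    brain_vol = np.empty(n_total)
    for grp, sel, bv_mean, bv_sd in (
        ("control", np.arange(cfg.n_control), 1066.0, 94.0),
        ("svd", np.arange(cfg.n_control, n_total), 1002.0, 116.0),
    ):
        p = cfg.wmh_lognormal_params[grp]
        mu, sigma = _lognormal_params(p["mean"], p["sd"])
        wmh[sel] = meta_rng.lognormal(mu, sigma, size=len(sel))
        lacunes[sel] = meta_rng.poisson(cfg.lacune_poisson_mean[grp], size=len(sel))
        brain_vol[sel] = meta_rng.normal(bv_mean, bv_sd, size=len(sel))
    age = meta_rng.normal(70.2, 9.5, size=n_total)
    sex = (meta_rng.random(n_total) < 0.40).astype(int)
    iq = meta_rng.normal(100.0, 12.0, size=n_total)

    svd_slice = slice(cfg.n_control, n_total)
    log_wmh_svd = np.log1p(wmh[svd_slice])
    severity = np.zeros(n_total)
    severity[svd_slice] = log_wmh_svd / log_wmh_svd.mean()
    # lesion-topography jitter: how hard a given lesion load hits each
    # connection class varies between patients (mean-1 lognormal per class)
    if cfg.lesion_jitter_sd > 0:
        sig = np.sqrt(np.log1p(cfg.lesion_jitter_sd**2))
        jitter = meta_rng.lognormal(-sig**2 / 2.0, sig, size=(n_total, 3))
    else:
        jitter = np.ones((n_total, 3))

    tables: dict[str, pd.DataFrame] = {}
    rich_raw = np.empty(n_total)
    for s in range(n_total):
        sample_seed, lesion_seed = seeds[2 + s].spawn(2)
        table = sample_subject_streamlines(
            template, cfg.subject_noise_sd, seed=sample_seed, subject_id=ids[s]
        )
        if groups[s] == "svd":
            table = apply_svd_lesion(
                table,
                classes,
                cfg.lesion_factors,
                np.minimum(severity[s] * jitter[s], SEVERITY_CAP),
                seed=lesion_seed,
            )
        tables[ids[s]] = table
        rich_raw[s] = _latent_rich_strength(table, classes, cfg.scale)

    rich_z = np.empty(n_total)
    for sel in (np.arange(cfg.n_control), np.arange(cfg.n_control, n_total)):
        vals = rich_raw[sel]
        sd = vals.std(ddof=0)
        rich_z[sel] = (vals - vals.mean()) / sd if sd > 0 else 0.0

    # cognition is generated per group (the case-control designs score
    # cognition within-study), so betas are standardized within each group
    cog_seeds = np.random.SeedSequence(cfg.seed + 1).spawn(4)
    speed = np.empty(n_total)
    executive = np.empty(n_total)
    for gidx, sel in enumerate(
        (np.arange(cfg.n_control), np.arange(cfg.n_control, n_total))
    ):
        speed[sel] = generate_cognition(
            rich_z[sel], lacunes[sel], cfg.cognition_coeffs, cog_seeds[gidx]
        )
        executive[sel] = generate_cognition(
            rich_z[sel], lacunes[sel], cfg.executive_coeffs, cog_seeds[2 + gidx]
        )

    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "age": age,
            "sex": sex,
            "iq_or_education": iq,
            "wmh_ml": wmh,
            "lacune_count": lacunes,
            "brain_volume_ml": brain_vol,
            "processing_speed_z": speed,
            "executive_z": executive,
        }
    )
    return Cohort(template=template, tables=tables, subjects=subjects, config=cfg)


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write streamlines, metadata, node labels, config and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "streamlines": outdir / "streamlines.tsv",
        "metadata": outdir / "metadata.tsv",
        "labels": outdir / "node_labels.txt",
        "config": outdir / "cohort_config.yaml",
        "manifest": outdir / "manifest.yaml",
    }
    combined = cohort.combined_table()
    combined.to_csv(paths["streamlines"], sep="\t", index=False, float_format="%.17g")
    cohort.subjects.to_csv(paths["metadata"], sep="\t", index=False, float_format="%.17g")
    with open(paths["labels"], "w") as fh:
        fh.write("\n".join(str(i + 1) for i in range(cohort.config.n_nodes)) + "\n")
    cohort.config.to_yaml(paths["config"])
    manifest = {
        "seed": cohort.config.seed,
        "n_subjects": int(len(cohort.subjects)),
        "n_streamlines": int(len(combined)),
        "hub_nodes_1based": [int(h) + 1 for h in cohort.template.hub_set],
        "files": {k: str(v.name) for k, v in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
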