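"""Weighted rich-club statistics, node selection and edge classification.

The weighted rich-club coefficient at degree threshold k is the summed weight
of edges among nodes of degree > k, divided by the sum of the equally many
strongest edge weights anywhere in the network.  Normalization divides by the
mean coefficient over degree-preserving random rewirings; values above 1
indicate rich-club organisation.  Edges are classified as RICH (both
endpoints in the rich set), FEEDER (exactly one) or PERIPHERAL (neither).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome
from .metrics import degree, randomize_preserving_degree, total_strength

logger = logging.getLogger(__name__)

RICH, FEEDER, PERIPHERAL = 1, 2, 3
CLASS_NAMES = {RICH: "rich", FEEDER: "feeder", PERIPHERAL: "peripheral"}

__all__ = [
    "RICH",
    "FEEDER",
    "PERIPHERAL",
    "CLASS_NAMES",
    "RichClubCurve",
    "EdgeClassMap",
    "ClassStrengths",
    "weighted_rich_club",
    "normalized_rich_club",
    "select_rich_nodes_group_mean",
    "select_rich_nodes_group_average_network",
    "select_rich_nodes_individual",
    "classify_edges",
    "pair_classes",
    "class_strengths",
    "length_median_split",
    "percent_reduction",
]


@dataclass
class RichClubCurve:
    k: np.ndarray
    phi: np.ndarray           # NaN where undefined (< 2 qualifying nodes or 0 edges)
    phi_rand: np.ndarray      # null mean, NaN where undefined in every null
    phi_norm: np.ndarray      # phi / phi_rand
    n_null: int


@dataclass
class EdgeClassMap:
    """Class code (RICH/FEEDER/PERIPHERAL) for every off-diagonal node pair."""

    rich_set: np.ndarray
    classes: np.ndarray  # (n, n) int8, 0 on the diagonal

    @property
    def n(self) -> int:
        return self.classes.shape[0]


@dataclass
class ClassStrengths:
    strengths: dict[str, float]
    counts: dict[str, int]
    ratio_rich_feeder: float
    ratio_rich_peripheral: float
    normalized_by_total: bool = False


def weighted_rich_club(connectome: Connectome, k: int) -> float:
    """Weighted rich-club coefficient phi(k); NaN where undefined."""
    if k < 0:
        raise ValueError("k must be non-negative")
    deg = degree(connectome)
    members = np.flatnonzero(deg > k)
    if len(members) < 2:
        return float("nan")
    sub = connectome.weights[np.ix_(members, members)]
    triu = np.triu(sub, 1)
    e_club = int(np.count_nonzero(triu))
    if e_club == 0:
        return float("nan")
    w_club = float(triu.sum())
    all_w = connectome.weights[np.triu_indices(connectome.n, 1)]
    all_w = all_w[all_w > 0]
    strongest = np.sort(all_w)[-e_club:]
    return w_club / float(strongest.sum())


def _phi_all_k(connectome: Connectome, ks: np.ndarray) -> np.ndarray:
    return np.array([weighted_rich_club(connectome, int(k)) for k in ks])


def normalized_rich_club(
    connectome: Connectome,
    k_range: np.ndarray | None = None,
    n_null: int = 100,
    seed: int | np.random.Generator = 0,
    n_swaps_per_edge: int = 10,
) -> RichClubCurve:
    """phi(k) normalized by the mean over degree-preserving random networks."""
    if n_null < 1:
        raise ValueError("n_null must be at least 1")
    rng = np.random.default_rng(seed)
    if k_range is None:
        kmax = int(degree(connectome).max(initial=0))
        k_range = np.arange(1, max(kmax, 2))
    ks = np.asarray(k_range, dtype=int)
    phi = _phi_all_k(connectome, ks)
    null_phi = np.full((n_null, len(ks)), np.nan)
    for r in range(n_null):
        null = randomize_preserving_degree(connectome, n_swaps_per_edge, rng)
        null_phi[r] = _phi_all_k(null, ks)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        phi_rand = np.nanmean(null_phi, axis=0)
    all_null_undefined = np.isnan(null_phi).all(axis=0) & ~np.isnan(phi)
    if all_null_undefined.any():
        warnings.warn(
            f"phi undefined in every null network at k={ks[all_null_undefined]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_norm = phi / phi_rand
    return RichClubCurve(ks, phi, phi_rand, phi_norm, n_null)


def _top_by_degree(
    score: np.ndarray, strength: np.ndarray, n_rich: int
) -> np.ndarray:
    """Top ``n_rich`` nodes by ``score``; ties broken by strength then index."""
    order = np.lexsort((np.arange(len(score)), -strength, -score))
    chosen = order[:n_rich]
    if n_rich < len(score) and score[order[n_rich - 1]] == score[order[n_rich]]:
        logger.warning(
            "tie at the rich-set cut (score %.6g): broken by node strength, "
            "then lower node index",
            score[order[n_rich]],
        )
    return np.sort(chosen)


def _node_strengths(connectome: Connectome) -> np.ndarray:
    return connectome.weights.sum(axis=0)


def select_rich_nodes_group_mean(
    connectomes: list[Connectome], n_rich: int = 8
) -> np.ndarray:
    """Top ``n_rich`` nodes by mean degree across all subjects of both groups."""
    if not connectomes:
        raise ValueError("need at least one connectome")
    if n_rich >= connectomes[0].n:
        raise ValueError("n_rich must be smaller than the node count")
    mean_deg = np.mean([degree(c) for c in connectomes], axis=0)
    mean_str = np.mean([_node_strengths(c) for c in connectomes], axis=0)
    return _top_by_degree(mean_deg, mean_str, n_rich)


def select_rich_nodes_group_average_network(
    connectomes: list[Connectome], prevalence: float = 0.30, n_rich: int = 8
) -> np.ndarray:
    """Rich nodes from the binary group-averaged network.

    An edge enters the group network if present in at least ``prevalence`` of
    subjects; rich nodes are the top ``n_rich`` by degree in that network.
    """
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must be in (0, 1]")
    if not connectomes:
        raise ValueError("need at least one connectome")
    presence = np.mean([(c.weights > 0) for c in connectomes], axis=0)
    group_adj = presence >= prevalence
    np.fill_diagonal(group_adj, False)
    deg = group_adj.sum(axis=0)
    mean_str = np.mean([_node_strengths(c) for c in connectomes], axis=0)
    return _top_by_degree(deg.astype(float), mean_str, n_rich)


def select_rich_nodes_individual(
    connectome: Connectome, top_fraction: float = 0.09
) -> np.ndarray:
    """Per-subject rich set: top ``round(top_fraction * n)`` nodes by degree."""
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    n_rich = max(1, round(top_fraction * connectome.n))
    return _top_by_degree(
        degree(connectome).astype(float), _node_strengths(connectome), n_rich
    )


def pair_classes(n_nodes: int, rich_set: np.ndarray) -> np.ndarray:
    """Class code for every off-diagonal node pair given the rich set."""
    rich_set = np.asarray(rich_set, dtype=int)
    if len(rich_set) and (rich_set.min() < 0 or rich_set.max() >= n_nodes):
        raise ValueError("rich node index out of range")
    is_rich = np.zeros(n_nodes, dtype=bool)
    is_rich[rich_set] = True
    n_rich_ends = is_rich[:, None].astype(int) + is_rich[None, :].astype(int)
    classes = np.where(
        n_rich_ends == 2, RICH, np.where(n_rich_ends == 1, FEEDER, PERIPHERAL)
    ).astype(np.int8)
    np.fill_diagonal(classes, 0)
    return classes


def classify_edges(connectome: Connectome, rich_set: np.ndarray) -> EdgeClassMap:
    """Partition the network's node pairs into rich/feeder/peripheral."""
    return EdgeClassMap(
        rich_set=np.asarray(rich_set, dtype=int),
        classes=pair_classes(connectome.n, rich_set),
    )


def class_strengths(
    connectome: Connectome,
    class_map: EdgeClassMap,
    normalize_by_total: bool = False,
) -> ClassStrengths:
    """Summed edge weight and edge count per connection class, plus ratios."""
    if class_map.n != connectome.n:
        raise ValueError("class map size must match the connectome")
    iu = np.triu_indices(connectome.n, 1)
    w = connectome.weights[iu]
    cls = class_map.classes[iu]
    present = w > 0
    strengths: dict[str, float] = {}
    counts: dict[str, int] = {}
    for code, name in CLASS_NAMES.items():
        sel = present & (cls == code)
        strengths[name] = float(w[sel].sum())
        counts[name] = int(sel.sum())
    if normalize_by_total:
        tot = total_strength(connectome)
        if tot > 0:
            strengths = {k: v / tot for k, v in strengths.items()}
    def _ratio(num: float, den: float) -> float:
        if den <= 0:
            warnings.warn("ratio undefined: empty denominator class")
            return float("nan")
        return num / den
    return ClassStrengths(
        strengths=strengths,
        counts=counts,
        ratio_rich_feeder=_ratio(strengths["rich"], strengths["feeder"]),
        ratio_rich_peripheral=_ratio(strengths["rich"], strengths["peripheral"]),
        normalized_by_total=normalize_by_total,
    )


def length_median_split(
    connectome: Connectome, class_map: EdgeClassMap
) -> dict[str, dict[str, dict[str, float]]]:
    """Median-split feeder and peripheral edges into short and long tracts.

    Within each class, edges with fibre length <= the class median go to
    "short", the rest to "long" (ties to short).  The rich class is reported
    undivided.  Returns, per subset, the summed strength, mean fibre length
    and edge count.
    """
    iu = np.triu_indices(connectome.n, 1)
    w = connectome.weights[iu]
    ln = connectome.mean_length[iu]
    cls = class_map.classes[iu]
    present = w > 0
    if np.any(present & (ln <= 0)):
        raise ValueError("mean_length must be defined on all present edges")

    def _summary(mask: np.ndarray) -> dict[str, float]:
        return {
            "strength": float(w[mask].sum()),
            "mean_length": float(ln[mask].mean()) if mask.any() else float("nan"),
            "n_edges": int(mask.sum()),
        }

    out: dict[str, dict[str, dict[str, float]]] = {
        "rich": {"all": _summary(present & (cls == RICH))}
    }
    for code, name in ((FEEDER, "feeder"), (PERIPHERAL, "peripheral")):
        sel = present & (cls == code)
        if not sel.any():
            out[name] = {"short": _summary(sel), "long": _summary(sel)}
            continue
        med = float(np.median(ln[sel]))
        out[name] = {
            "short": _summary(sel & (ln <= med)),
            "long": _summary(sel & (ln > med)),
        }
    return out


def percent_reduction(control_values, patient_values) -> float:
    """Percent reduction of the patient mean relative to the control mean."""
    mc = float(np.mean(control_values))
    mp = float(np.mean(patient_values))
    if mc <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (mc - mp) / mc
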