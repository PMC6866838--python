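"""Global graph measures and degree-preserving null-model normalization.

Distances on a strength-weighted connectome use the standard convention that
an edge of weight w has traversal length 1/w, so strong connections are
short.  Efficiency is the mean inverse shortest-path distance; disconnected
pairs contribute 0, which keeps the measure comparable across networks of
different density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectome import Connectome

__all__ = [
    "GraphSummary",
    "degree",
    "density",
    "total_strength",
    "global_efficiency",
    "local_efficiency",
    "randomize_preserving_degree",
    "normalized_efficiencies",
    "graph_summary",
]


@dataclass
class GraphSummary:
    degree: np.ndarray
    density: float
    total_strength: float
    global_efficiency: float
    local_efficiency: float
    norm_global_efficiency: float = float("nan")
    norm_local_efficiency: float = float("nan")


def degree(connectome: Connectome) -> np.ndarray:
    """Number of connections of each node."""
    return (connectome.weights > 0).sum(axis=0).astype(int)


def density(connectome: Connectome) -> float:
    """Fraction of possible node pairs that are connected."""
    n = connectome.n
    return connectome.n_edges() / (n * (n - 1) / 2)

def total_strength(connectome: Connectome) -> float:
    """Sum of all connection strengths (each edge counted once)."""
    return float(np.triu(connectome.weights, 1).sum())


def _shortest_paths(weights: np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path distances with length 1/w per edge."""
    mask = weights > 0
    if not mask.any():
        n = weights.shape[0]
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    lengths = np.zeros_like(weights)
    lengths[mask] = 1.0 / weights[mask]
    return dijkstra(csr_matrix(lengths), directed=False)


def _efficiency_from_weights(weights: np.ndarray) -> float:
    n = weights.shape[0]
    if n < 2:
        return 0.0
    d = _shortest_paths(weights)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def global_efficiency(connectome: Connectome) -> float:
    """Mean inverse shortest-path distance over all ordered node pairs."""
    return _efficiency_from_weights(connectome.weights)


def local_efficiency(connectome: Connectome) -> float:
    """Mean, over nodes, of the efficiency of each node's neighbour subgraph.

    Nodes with fewer than two neighbours contribute 0.
    """
    w = connectome.weights
    n = connectome.n
    total = 0.0
    for u in range(n):
        nbrs = np.flatnonzero(w[u] > 0)
        if len(nbrs) < 2:
            continue
        total += _efficiency_from_weights(w[np.ix_(nbrs, nbrs)])
    return total / n


def randomize_preserving_degree(
    connectome: Connectome,
    n_swaps_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
) -> Connectome:
    """Degree-preserving (Maslov–Sneppen) rewiring with weights kept on edges.

    Repeated double-edge swaps (a–b, c–d) -> (a–d, c–b); proposals creating
    self-loops or duplicate edges are rejected and retried.  The degree
    sequence and the multiset of edge weights are preserved exactly.  If no
    valid swap can be performed (e.g. a triangle) the input is returned
    unchanged with a warning.
    """
    rng = np.random.default_rng(seed)
    iu, ju = np.nonzero(np.triu(connectome.weights, 1))
    m = len(iu)
    if m < 2:
        warnings.warn("fewer than 2 edges: returning the input unchanged")
        return connectome.copy()
    ends = np.stack([iu, ju], axis=1)
    wvals = connectome.weights[iu, ju].copy()
    lvals = connectome.mean_length[iu, ju].copy()
    present = {(int(a), int(b)) for a, b in ends}
    target = n_swaps_per_edge * m
    max_attempts = max(100, 50 * target)
    done = 0
    attempts = 0
    # draw proposal indices in batches to amortize RNG overhead
    batch = rng.integers(0, m, size=(max_attempts, 2))
    flip = rng.random(max_attempts) < 0.5
    for t in range(max_attempts):
        if done >= target:
            break
        attempts += 1
        e1, e2 = batch[t]
        if e1 == e2:
            continue
        a, b = ends[e1]
        c, d = ends[e2]
        if flip[t]:
            c, d = d, c
        # propose (a-d, c-b)
        if a == d or c == b:
            continue
        p1 = (min(a, d), max(a, d))
        p2 = (min(c, b), max(c, b))
        if p1 in present or p2 in present:
            continue
        present.discard((min(a, b), max(a, b)))
        present.discard((min(ends[e2][0], ends[e2][1]), max(ends[e2][0], ends[e2][1])))
        present.add(p1)
        present.add(p2)
        ends[e1] = p1
        ends[e2] = p2
        done += 1
    if done == 0:
        warnings.warn("no valid degree-preserving swaps found: input returned unchanged")
        return connectome.copy()
    n = connectome.n
    w = np.zeros((n, n))
    ml = np.zeros((n, n))
    w[ends[:, 0], ends[:, 1]] = wvals
    ml[ends[:, 0], ends[:, 1]] = lvals
    w = w + w.T
    ml = ml + ml.T
    return Connectome(w, ml, list(connectome.labels))


def normalized_efficiencies(
    connectome: Connectome,
    n_null: int = 100,
    seed: int | np.random.Generator = 0,
    n_swaps_per_edge: int = 10,
    include_local: bool = True,
) -> tuple[float, float]:
    """Efficiencies divided by their mean over degree-matched random networks.

    Returns ``(norm_global, norm_local)``; ``norm_local`` is NaN when
    ``include_local`` is False.  A zero null mean yields NaN with a warning.
    """
    if n_null < 1:
        raise ValueError("n_null must be at least 1")
    rng = np.random.default_rng(seed)
    ge = global_efficiency(connectome)
    le = local_efficiency(connectome) if include_local else float("nan")
    null_ge = np.empty(n_null)
    null_le = np.empty(n_null)
    for r in range(n_null):
        null = randomize_preserving_degree(connectome, n_swaps_per_edge, rng)
        null_ge[r] = global_efficiency(null)
        null_le[r] = local_efficiency(null) if include_local else np.nan
    mg = null_ge.mean()
    if mg == 0:
        warnings.warn("null global efficiency is zero: normalization undefined")
        return float("nan"), float("nan")
    norm_g = ge / mg
    norm_l = float("nan")
    if include_local:
        ml = null_le.mean()
        if ml == 0:
            warnings.warn("null local efficiency is zero: normalization undefined")
        else:
            norm_l = le / ml
    return float(norm_g), float(norm_l)


def graph_summary(
    connectome: Connectome,
    n_null: int = 0,
    seed: int | np.random.Generator = 0,
) -> GraphSummary:
    """Assemble the standard global measures; normalized ones when n_null > 0."""
    summary = GraphSummary(
        degree=degree(connectome),
        density=density(connectome),
        total_strength=total_strength(connectome),
        global_efficiency=global_efficiency(connectome),
        local_efficiency=local_efficiency(connectome),
    )
    if n_null > 0:
        ng, nl = normalized_efficiencies(connectome, n_null=n_null, seed=seed)
        summary.norm_global_efficiency = ng
        summary.norm_local_efficiency = nl
    return summary
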