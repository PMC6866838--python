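"""Independent brute-force reference implementations used only by tests.

These deliberately use naive enumeration (explicit loops, Floyd-Warshall)
and share no code with the package, so they can serve as oracles.
"""

import numpy as np


def floyd_warshall_distances(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths with edge traversal length 1/w, by relaxation."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_global_efficiency(weights: np.ndarray) -> float:
    n = weights.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall_distances(weights)
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                acc += 1.0 / d[i, j]
    return acc / (n * (n - 1))


def brute_local_efficiency(weights: np.ndarray) -> float:
    n = weights.shape[0]
    acc = 0.0
    for u in range(n):
        nbrs = [v for v in range(n) if weights[u, v] > 0]
        if len(nbrs) < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        acc += brute_global_efficiency(sub)
    return acc / n


def brute_weighted_rich_club(weights: np.ndarray, k: int) -> float:
    """Explicit enumeration of the club, its edges, and the global top weights."""
    n = weights.shape[0]
    deg = [sum(1 for j in range(n) if j != i and weights[i, j] > 0) for i in range(n)]
    club = [i for i in range(n) if deg[i] > k]
    if len(club) < 2:
        return float("nan")
    club_weights = []
    for a in range(len(club)):
        for b in range(a + 1, len(club)):
            w = weights[club[a], club[b]]
            if w > 0:
                club_weights.append(w)
    if not club_weights:
        return float("nan")
    all_weights = sorted(
        (weights[i, j] for i in range(n) for j in range(i + 1, n) if weights[i, j] > 0),
        reverse=True,
    )
    top = all_weights[: len(club_weights)]
    return sum(club_weights) / sum(top)


def random_weighted_graph(rng: np.random.Generator, n: int, p: float = 0.5) -> np.ndarray:
    """Random symmetric weighted adjacency matrix for oracle comparisons."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w[i, j] = w[j, i] = rng.uniform(0.1, 5.0)
    return w
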