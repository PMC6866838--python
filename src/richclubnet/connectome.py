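"""Weighted structural connectomes built from streamline endpoint tables.

A connectome here is a symmetric, zero-diagonal, non-negative weight matrix
over a fixed parcellation (90 cerebral regions by default), together with the
mean streamline length of every present edge.  The primary edge weight is the
sum of inverse streamline lengths, times a user-supplied scaling constant that
absorbs the seeding density of the tractography; an alternative weighting
(streamline count normalized by region volume) is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STREAMLINE_COLUMNS = ("subject_id", "node_i", "node_j", "length_mm")

__all__ = [
    "Connectome",
    "STREAMLINE_COLUMNS",
    "build_connectome",
    "build_connectomes",
    "build_connectome_count_by_volume",
    "threshold_edges",
    "read_streamline_table",
    "write_streamline_table",
    "read_connectome",
    "write_connectome",
]


@dataclass
class Connectome:
    """Symmetric weighted network over a fixed node set.

    Parameters
    ----------
    weights
        ``(n, n)`` non-negative symmetric matrix with zero diagonal.
        A zero entry means "no connection".
    mean_length
        ``(n, n)`` matrix of mean streamline length (mm) per edge; zero
        wherever ``weights`` is zero.
    labels
        Node names, one per row; defaults to 1-based integer strings.
    """

    weights: np.ndarray
    mean_length: np.ndarray = None  # type: ignore[assignment]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be a square matrix")
        if self.weights.shape[0] < 3:
            raise ValueError("a connectome needs at least 3 nodes")
        if not np.allclose(self.weights, self.weights.T, rtol=0, atol=0):
            raise ValueError("weights must be exactly symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weights must have a zero diagonal")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.mean_length is None:
            self.mean_length = np.zeros_like(self.weights)
        self.mean_length = np.asarray(self.mean_length, dtype=float)
        if self.mean_length.shape != self.weights.shape:
            raise ValueError("mean_length shape must match weights")
        if not self.labels:
            self.labels = [str(i + 1) for i in range(self.n)]
        if len(self.labels) != self.n:
            raise ValueError("labels length must match node count")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def edge_mask(self) -> np.ndarray:
        """Boolean matrix marking present edges."""
        return self.weights > 0

    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def copy(self) -> "Connectome":
        return Connectome(self.weights.copy(), self.mean_length.copy(), list(self.labels))


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STREAMLINE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"streamline table missing columns: {missing}")
    return table


def build_connectome(
    table: pd.DataFrame, n_nodes: int = 90, scale: float = 1.0
) -> Connectome:
    """Build one subject's weighted connectome from its streamline table.

    The weight of edge (i, j) is ``scale * sum_f 1/length_f`` over all
    streamlines f with endpoints in regions i and j; ``mean_length`` is the
    arithmetic mean of those lengths.  Self-connections (i == j) are dropped.
    ``scale`` is a single positive constant correcting for seeding density; it
    rescales all weights uniformly, so ratio- and classification-based results
    downstream do not depend on it.
    """
    _validate_table(table)
    if scale <= 0:
        raise ValueError("scale must be positive")
    if n_nodes < 3:
        raise ValueError("n_nodes must be at least 3")
    w = np.zeros((n_nodes, n_nodes))
    lsum = np.zeros((n_nodes, n_nodes))
    cnt = np.zeros((n_nodes, n_nodes))
    if len(table) == 0:
        warnings.warn("empty streamline table: returning an all-zero connectome")
        return Connectome(w, np.zeros_like(w))
    i = np.asarray(table["node_i"], dtype=int)
    j = np.asarray(table["node_j"], dtype=int)
    length = np.asarray(table["length_mm"], dtype=float)
    if np.any((i < 1) | (i > n_nodes) | (j < 1) | (j > n_nodes)):
        bad = table[(i < 1) | (i > n_nodes) | (j < 1) | (j > n_nodes)]
        raise ValueError(
            f"node labels outside parcellation 1..{n_nodes}: "
            f"first offending row {bad.index[0]}"
        )
    if np.any(length <= 0):
        raise ValueError("streamline lengths must be positive")
    keep = i != j  # self-connections are discarded
    i, j, length = i[keep] - 1, j[keep] - 1, length[keep]
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    np.add.at(w, (lo, hi), 1.0 / length)
    np.add.at(lsum, (lo, hi), length)
    np.add.at(cnt, (lo, hi), 1.0)
    w *= scale
    w = w + w.T
    lsum, cnt = lsum + lsum.T, cnt + cnt.T
    with np.errstate(invalid="ignore"):
        mean_length = np.where(cnt > 0, lsum / np.maximum(cnt, 1), 0.0)
    return Connectome(w, mean_length)


def build_connectomes(
    table: pd.DataFrame, n_nodes: int = 90, scale: float = 1.0
) -> dict[str, Connectome]:
    """Build one connectome per ``subject_id`` in a multi-subject table."""
    _validate_table(table)
    out: dict[str, Connectome] = {}
    for sid, sub in table.groupby("subject_id", sort=True):
        out[str(sid)] = build_connectome(sub, n_nodes=n_nodes, scale=scale)
    return out


def build_connectome_count_by_volume(
    table: pd.DataFrame, roi_volumes: np.ndarray, n_nodes: int | None = None
) -> Connectome:
    """Alternative weighting: streamline count normalized by region volume.

    ``w_ij = count_ij / ((vol_i + vol_j) / 2)``.  The symmetric mean of the
    two region volumes is used as the normalizer.
    """
    roi_volumes = np.asarray(roi_volumes, dtype=float)
    if np.any(roi_volumes <= 0):
        raise ValueError("roi_volumes must be positive for every node")
    n = len(roi_volumes) if n_nodes is None else n_nodes
    if len(roi_volumes) != n:
        raise ValueError("roi_volumes length must equal n_nodes")
    base = build_connectome(table, n_nodes=n, scale=1.0)
    cnt = np.zeros((n, n))
    sub = table[table["node_i"] != table["node_j"]]
    if len(sub):
        i = np.asarray(sub["node_i"], dtype=int) - 1
        j = np.asarray(sub["node_j"], dtype=int) - 1
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        np.add.at(cnt, (lo, hi), 1.0)
        cnt = cnt + cnt.T
    volmean = (roi_volumes[:, None] + roi_volumes[None, :]) / 2.0
    w = cnt / volmean
    np.fill_diagonal(w, 0.0)
    return Connectome(w, base.mean_length)


def threshold_edges(connectome: Connectome, tau: float = 1.0) -> Connectome:
    """Remove edges with weight below ``tau`` (weights equal to tau are kept).

    Thresholding suppresses noise-related false-positive connections from the
    tractography.  Idempotent at fixed tau.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    out = connectome.copy()
    kill = (out.weights < tau) & (out.weights > 0)
    out.weights[kill] = 0.0
    out.mean_length[kill] = 0.0
    return out


# ---------------------------------------------------------------------------
# Plain-text IO.  Streamline tables and adjacency matrices are tab-delimited;
# matrices carry a label header row, and mean lengths live in a sibling
# "<stem>.lengths.tsv" file.
# ---------------------------------------------------------------------------

def read_streamline_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _validate_table(table)
    for col in ("node_i", "node_j"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            # +2: one for the header, one for 1-based line numbering
            raise ValueError(
                f"malformed {col} at line {int(np.flatnonzero(bad)[0]) + 2} of {path}"
            )
        table[col] = vals.astype(int)
    lengths = pd.to_numeric(table["length_mm"], errors="coerce")
    bad = lengths.isna() | (lengths <= 0)
    if bad.any():
        raise ValueError(
            f"malformed length_mm at line {int(np.flatnonzero(bad)[0]) + 2} of {path}"
        )
    table["length_mm"] = lengths.astype(float)
    return table


def write_streamline_table(table: pd.DataFrame, path) -> None:
    _validate_table(table)
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _lengths_path(path) -> str:
    path = str(path)
    stem = path[: -len(".tsv")] if path.endswith(".tsv") else path
    return stem + ".lengths.tsv"


def write_connectome(connectome: Connectome, path) -> None:
    """Write the weight matrix (with label header) plus a lengths sidecar."""
    frame = pd.DataFrame(
        connectome.weights, columns=connectome.labels, index=connectome.labels
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    lengths = pd.DataFrame(
        connectome.mean_length, columns=connectome.labels, index=connectome.labels
    )
    lengths.to_csv(_lengths_path(path), sep="\t", index=False, float_format="%.17g")


def read_connectome(path) -> Connectome:
    import os

    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    w = frame.to_numpy(dtype=float)
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({w.shape})")
    if not np.array_equal(w, w.T):
        raise ValueError(f"{path}: adjacency matrix is not symmetric")
    lengths = None
    lp = _lengths_path(path)
    if os.path.exists(lp):
        lengths = pd.read_csv(lp, sep="\t", float_precision="round_trip").to_numpy(dtype=float)
    return Connectome(w, lengths, [str(c) for c in frame.columns])
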