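"""Group inference: Welch tests, permutation FWE, regression and mediation.

Implements the statistical toolkit used for case-control connectome
comparisons: Welch's unequal-variance t-test with Satterthwaite degrees of
freedom, label-permutation family-wise-error control (max-statistic over a
small family of measures, or a network-based-statistic style edge-cluster
variant), covariate-adjusted group differences, standardized multiple
regression with variance-inflation-factor diagnostics, and the classical
Sobel test of an indirect (mediated) effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GroupTestResult",
    "PermutationResult",
    "RegressionResult",
    "MediationResult",
    "log_transform",
    "sobel_z",
    "welch_t",
    "permutation_fwe",
    "adjusted_group_difference",
    "standardized_regression",
    "sobel_mediation",
    "correlate_markers",
]


@dataclass
class GroupTestResult:
    statistic: float
    df: float
    p_raw: float
    mean_x: float
    mean_y: float
    p_fwe: float | None = None
    estimate: float = float("nan")  # group coefficient when covariate-adjusted

    @property
    def percent_reduction(self) -> float:
        """Reduction of the second group's mean relative to the first's."""
        if self.mean_x <= 0:
            return float("nan")
        return 100.0 * (self.mean_x - self.mean_y) / self.mean_x


@dataclass
class PermutationResult:
    p_fwe: np.ndarray
    t_observed: np.ndarray
    mode: str
    n_perm: int


@dataclass
class RegressionResult:
    beta: "pd.Series"
    pvalues: "pd.Series"
    r_squared: float
    vif: "pd.Series"
    multicollinearity: bool


@dataclass
class MediationResult:
    a: float
    se_a: float
    b: float
    se_b: float
    indirect: float
    sobel_z: float
    p_two_sided: float


def log_transform(values) -> np.ndarray:
    """ln(1 + x), elementwise; used to normalize WMH volumes and lacune counts."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("log_transform requires non-negative values")
    return np.log1p(values)


def welch_t(x, y) -> GroupTestResult:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance")
    n1, n2 = len(x), len(y)
    sem2 = vx / n1 + vy / n2
    t = (x.mean() - y.mean()) / np.sqrt(sem2)
    df = sem2**2 / ((vx / n1) ** 2 / (n1 - 1) + (vy / n2) ** 2 / (n2 - 1))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return GroupTestResult(float(t), float(df), float(p), float(x.mean()), float(y.mean()))


def _welch_t_columns(X: np.ndarray, g1: np.ndarray) -> np.ndarray:
    """Vectorized Welch |t| for every column of X; 0 where variance vanishes."""
    a, b = X[g1], X[~g1]
    n1, n2 = len(a), len(b)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sem2 = va / n1 + vb / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sem2)
    return np.where(sem2 > 0, np.abs(t), 0.0)


def permutation_fwe(
    measures_matrix,
    group_labels,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    mode: str = "max-stat",
    primary_threshold: float = 3.0,
    edge_index: list[tuple[int, int]] | None = None,
    n_nodes: int | None = None,
) -> PermutationResult:
    """Family-wise-error corrected p-values by permutation of group labels.

    mode "max-stat": per permutation, the maximum Welch |t| over measures is
    recorded; each measure's p_fwe is the add-one (Phipson-Smyth) tail
    probability of that null maximum, a valid FWE correction for a small
    family of summary measures.

    mode "edge-cluster": measures are edges of a network (``edge_index``
    giving the node pair of each column); per permutation, edges with
    |t| >= ``primary_threshold`` are kept and the size (edge count) of the
    largest connected component forms the null.  Observed suprathreshold
    components get the cluster-level p of their size; other edges get 1.
    """
    X = np.asarray(measures_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("group_labels must contain exactly two groups")
    g1 = labels == uniq[0]
    rng = np.random.default_rng(seed)
    t_obs = _welch_t_columns(X, g1)

    if mode == "max-stat":
        null_max = np.empty(n_perm)
        for p in range(n_perm):
            null_max[p] = _welch_t_columns(X, rng.permutation(g1)).max()
        p_fwe = (1.0 + (null_max[:, None] >= t_obs[None, :]).sum(axis=0)) / (1.0 + n_perm)
        return PermutationResult(p_fwe, t_obs, mode, n_perm)

    if mode == "edge-cluster":
        if edge_index is None or n_nodes is None:
            raise ValueError("edge-cluster mode needs edge_index and n_nodes")
        ei = np.asarray(edge_index)

        def _largest_cluster(tvals: np.ndarray) -> tuple[int, np.ndarray]:
            keep = tvals >= primary_threshold
            if not keep.any():
                return 0, np.full(len(tvals), -1)
            sub = ei[keep]
            adj = coo_matrix(
                (np.ones(len(sub)), (sub[:, 0], sub[:, 1])), shape=(n_nodes, n_nodes)
            )
            n_comp, member = connected_components(adj + adj.T, directed=False)
            comp_of_edge = np.full(len(tvals), -1)
            comp_of_edge[keep] = member[sub[:, 0]]
            sizes = np.bincount(member[sub[:, 0]], minlength=n_comp)
            return int(sizes.max()), comp_of_edge

        null_max = np.empty(n_perm, dtype=int)
        for p in range(n_perm):
            null_max[p], _ = _largest_cluster(
                _welch_t_columns(X, rng.permutation(g1))
            )
        _, comp_of_edge = _largest_cluster(t_obs)
        p_fwe = np.ones(X.shape[1])
        for comp in np.unique(comp_of_edge[comp_of_edge >= 0]):
            size = int((comp_of_edge == comp).sum())
            p_val = (1.0 + (null_max >= size).sum()) / (1.0 + n_perm)
            p_fwe[comp_of_edge == comp] = p_val
        return PermutationResult(p_fwe, t_obs, mode, n_perm)

    raise ValueError(f"unknown mode {mode!r}")


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = []
        for idx, col in enumerate(design.columns):
            others = np.delete(X, idx, axis=1)
            resid = X[:, idx] - others @ np.linalg.lstsq(others, X[:, idx], rcond=None)[0]
            denom = X[:, idx].var() * len(X)
            if denom == 0 or resid @ resid < 1e-10 * max(denom, 1e-12):
                collinear.append(str(col))
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def adjusted_group_difference(
    outcome, group, covariates: pd.DataFrame | None = None
) -> GroupTestResult:
    """Group effect on the outcome from an OLS fit with covariates."""
    outcome = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    uniq = np.unique(group)
    if len(uniq) != 2:
        raise ValueError("group must have exactly two levels")
    g = (group == uniq[1]).astype(float)  # 1 = second (patient) level
    design = pd.DataFrame({"const": np.ones(len(outcome)), "group": g})
    if covariates is not None and len(covariates.columns):
        design = pd.concat([design, covariates.reset_index(drop=True)], axis=1)
    _check_full_rank(design)
    fit = sm.OLS(outcome, design).fit()
    return GroupTestResult(
        statistic=float(fit.tvalues["group"]),
        df=float(fit.df_resid),
        p_raw=float(fit.pvalues["group"]),
        mean_x=float(outcome[g == 0].mean()),
        mean_y=float(outcome[g == 1].mean()),
        estimate=float(fit.params["group"]),
    )


def _zscore_continuous(frame: pd.DataFrame) -> pd.DataFrame:
    """z-score continuous columns; binary (two-valued) columns pass through."""
    out = frame.copy().astype(float)
    for col in out.columns:
        vals = out[col]
        if vals.nunique() <= 2:
            continue
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"column {col!r} is constant")
        out[col] = (vals - vals.mean()) / sd
    return out


def standardized_regression(
    outcome, predictor, covariates: pd.DataFrame | None = None
) -> RegressionResult:
    """OLS with z-scored outcome and continuous predictors.

    Reports standardized coefficients, p-values, R^2 and the variance
    inflation factor per predictor; multicollinearity is flagged when any
    VIF exceeds 5.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    y = np.asarray(outcome, dtype=float)
    frame = pd.DataFrame({"predictor": np.asarray(predictor, dtype=float)})
    if covariates is not None and len(covariates.columns):
        frame = pd.concat([frame, covariates.reset_index(drop=True)], axis=1)
    if len(y) <= frame.shape[1] + 2:
        raise ValueError("too few observations for the number of predictors")
    frame = _zscore_continuous(frame)
    ysd = y.std(ddof=1)
    if ysd == 0:
        raise ValueError("outcome is constant")
    yz = (y - y.mean()) / ysd
    design = sm.add_constant(frame)
    _check_full_rank(design)
    fit = sm.OLS(yz, design).fit()
    exog = design.to_numpy(dtype=float)
    vif = pd.Series(
        [variance_inflation_factor(exog, i + 1) for i in range(frame.shape[1])],
        index=frame.columns,
    )
    return RegressionResult(
        beta=fit.params.drop("const"),
        pvalues=fit.pvalues.drop("const"),
        r_squared=float(fit.rsquared),
        vif=vif,
        multicollinearity=bool((vif > 5).any()),
    )


def sobel_z(a: float, se_a: float, b: float, se_b: float) -> float:
    """Sobel statistic z = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2); 0 when a*b = 0."""
    denom = np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    return 0.0 if denom == 0 else float(a * b / denom)


def sobel_mediation(
    X, M, Y, covariates: pd.DataFrame | None = None
) -> MediationResult:
    """Sobel test of the indirect path X -> M -> Y.

    The a path is from ``M ~ X + covariates``, the b path from
    ``Y ~ M + X + covariates``; z = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2) with
    a two-sided standard-normal p-value.
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    Y = np.asarray(Y, dtype=float)
    ncov = 0 if covariates is None else covariates.shape[1]
    if len(X) <= ncov + 3:
        raise ValueError("too few observations for mediation")
    cov = (
        covariates.reset_index(drop=True)
        if covariates is not None and len(covariates.columns)
        else pd.DataFrame(index=range(len(X)))
    )
    design_a = pd.concat(
        [pd.DataFrame({"const": 1.0, "X": X}), cov], axis=1
    )
    fit_a = sm.OLS(M, design_a).fit()
    a, se_a = float(fit_a.params["X"]), float(fit_a.bse["X"])
    design_b = pd.concat(
        [pd.DataFrame({"const": 1.0, "M": M, "X": X}), cov], axis=1
    )
    fit_b = sm.OLS(Y, design_b).fit()
    b, se_b = float(fit_b.params["M"]), float(fit_b.bse["M"])
    if not (np.isfinite(se_a) and np.isfinite(se_b)) or se_a == 0 or se_b == 0:
        raise ValueError("degenerate regression fit in mediation model")
    z = sobel_z(a, se_a, b, se_b)
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return MediationResult(a, se_a, b, se_b, a * b, z, float(p))


def correlate_markers(
    class_strength_table: pd.DataFrame,
    markers: pd.DataFrame,
    total_strength,
) -> pd.DataFrame:
    """Pearson correlations of SVD markers with strength-corrected class strengths.

    Marker columns (e.g. WMH volume, lacune count) are log1p-transformed;
    each class-strength column is first corrected for overall connectivity by
    taking the residual from a regression on total network strength.  Returns
    a long-format table with columns marker / measure / r / p / n.
    """
    tot = np.asarray(total_strength, dtype=float)
    n = len(tot)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    rows = []
    design = sm.add_constant(tot)
    for measure in class_strength_table.columns:
        resid = sm.OLS(
            np.asarray(class_strength_table[measure], dtype=float), design
        ).fit().resid
        for marker in markers.columns:
            vals = log_transform(markers[marker])
            r, p = scipy.stats.pearsonr(vals, resid)
            rows.append(
                {"marker": marker, "measure": measure, "r": float(r), "p": float(p), "n": n}
            )
    return pd.DataFrame(rows)
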