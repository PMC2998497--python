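"""The inference chain: Spearman, partial rank correlation, OLS, PCA, group tests.

All correlation machinery here is rank-based.  The partial correlation is a
partial *Spearman*: every vector is rank-transformed first, then the Pearson
partial correlation of the ranks given the control ranks is taken, either by
inverting the rank correlation matrix or by double residualization — the two
routes are algebraically identical and both are exposed so they can be
cross-checked.  PCA runs on the correlation matrix (z-scored columns),
because the covariates mix counts, expression levels and distances on wildly
different scales; components with eigenvalue >= 1 are flagged as retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "PCAResult",
    "GroupComparisonResult",
    "spearman",
    "partial_spearman",
    "multivariate_regression",
    "pca_determinants",
    "mann_whitney",
    "fisher_exact",
]


class DegenerateInputError(ValueError):
    """Constant vector / singular control structure: statistic undefined."""


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    rho: float
    p_value: float
    n: int
    controls: tuple[str, ...] = ()


@dataclass(frozen=True)
class PredictorStats:
    name: str
    coefficient: float
    std_error: float
    t_value: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    predictors: tuple[PredictorStats, ...]
    n: int
    r_squared: float
    intercept: float

    def predictor(self, name: str) -> PredictorStats:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)


@dataclass(frozen=True)
class PCAResult:
    variable_names: tuple[str, ...]
    eigenvalues: np.ndarray  # descending
    loadings: np.ndarray  # variables x components, orthonormal columns
    retained: np.ndarray  # bool per component (eigenvalue >= 1)
    scores: np.ndarray  # observations x components
    variance_fractions: np.ndarray

    @property
    def pc1_scores(self) -> np.ndarray:
        return self.scores[:, 0]

    def loading(self, variable: str, component: int = 0) -> float:
        return float(self.loadings[self.variable_names.index(variable), component])


@dataclass(frozen=True)
class GroupComparisonResult:
    group_names: tuple[str, str]
    group_sizes: tuple[int, int]
    group_means: tuple[float, float]
    u_statistic: float
    p_value: float


def _as_clean_vector(v: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN; restrict to complete cases first")
    return arr


def _rank(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def _t_p_value(r: float, df: int) -> float:
    """Two-sided p for a correlation r via the t transform with df degrees of freedom."""
    r = min(max(r, -1.0), 1.0)
    if df <= 0:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


_PERM_CACHE: dict[int, np.ndarray] = {}


def _all_permutations(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) int8 index table (cached)."""
    if n in _PERM_CACHE:
        return _PERM_CACHE[n]
    perms = np.zeros((1, 1), dtype=np.int8)
    for k in range(2, n + 1):
        perms = np.concatenate(
            [np.insert(perms, i, k - 1, axis=1) for i in range(k)]
        )
    _PERM_CACHE[n] = perms
    return perms


def _exact_pairing_p(rx: np.ndarray, ry: np.ndarray) -> float:
    """Exact two-sided p for rank correlation by enumerating all pairings.

    rho is affine in S = sum_i rx_i * ry_perm(i) with a positive scale, so
    the two-sided tail on |rho| equals the tail on |S - n * mean_rx * mean_ry|.
    """
    n = rx.size
    perms = _all_permutations(n)
    center = n * rx.mean() * ry.mean()
    s_obs = float(rx @ ry)
    obs_dev = abs(s_obs - center) * (1.0 - 1e-12)
    count = 0
    chunk = 500_000
    for start in range(0, perms.shape[0], chunk):
        s = ry[perms[start : start + chunk]] @ rx
        count += int(np.count_nonzero(np.abs(s - center) >= obs_dev))
    return count / perms.shape[0]


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    x_name: str = "x",
    y_name: str = "y",
    p_floor: Optional[float] = None,
) -> CorrelationResult:
    """Spearman rank correlation with an exact small-sample p-value.

    rho is the Pearson correlation of average ranks (ties share their mean
    rank).  The two-sided p comes from the t transform with n-2 df for
    n > 10, and from exact enumeration of all pairings for n <= 10.
    ``p_floor`` optionally clips the reported p from below, for display
    parity with statistics packages that floor tiny p-values.
    """
    xa = _as_clean_vector(x, x_name)
    ya = _as_clean_vector(y, y_name)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise DegenerateInputError("constant vector: Spearman correlation undefined")
    rx, ry = _rank(xa), _rank(ya)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n > 10:
        p = _t_p_value(rho, n - 2)
    else:
        p = _exact_pairing_p(rx, ry)
    if p_floor is not None:
        p = max(p, p_floor)
    return CorrelationResult(x_name, y_name, rho, p, n)


def _partial_from_corr(corr: np.ndarray) -> float:
    """Partial correlation of variables 0 and 1 given the rest, via precision matrix."""
    if np.linalg.cond(corr) > 1e12:
        raise DegenerateInputError("singular correlation structure among ranks")
    try:
        precision = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(f"singular correlation structure: {exc}") from None
    denom = precision[0, 0] * precision[1, 1]
    if denom <= 0:
        raise DegenerateInputError("non-positive precision diagonal")
    return float(-precision[0, 1] / math.sqrt(denom))


def _partial_by_residualization(
    rx: np.ndarray, ry: np.ndarray, controls: np.ndarray
) -> float:
    design = np.column_stack([np.ones(rx.size), controls])
    beta_x, _, rank, _ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    if rank < design.shape[1]:
        raise DegenerateInputError("collinear control variables")
    res_x = rx - design @ beta_x
    res_y = ry - design @ beta_y
    if np.allclose(res_x, 0) or np.allclose(res_y, 0):
        raise DegenerateInputError("a variable is fully explained by the controls")
    return float(np.corrcoef(res_x, res_y)[0, 1])


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    controls: Sequence[Sequence[float]],
    x_name: str = "x",
    y_name: str = "y",
    control_names: Optional[Sequence[str]] = None,
    method: Literal["inversion", "residualization"] = "inversion",
) -> CorrelationResult:
    """Partial Spearman correlation of x and y controlling one or more covariates.

    All vectors are rank-transformed, then the Pearson partial correlation
    of the ranks is computed by the requested route.  The two-sided p uses
    the t transform with df = n - 2 - (number of controls).  With an empty
    control set this reduces to :func:`spearman` (large-sample p).
    """
    xa = _as_clean_vector(x, x_name)
    ya = _as_clean_vector(y, y_name)
    ctrl = [np.asarray(c, dtype=float) for c in controls]
    k = len(ctrl)
    if control_names is None:
        control_names = tuple(f"z{i + 1}" for i in range(k))
    n = xa.size
    if ya.size != n or any(c.size != n for c in ctrl):
        raise ValueError("all vectors must have equal length")
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} observations for {k} controls")
    for v, name in [(xa, x_name), (ya, y_name)] + list(zip(ctrl, control_names)):
        if np.all(v == v[0]):
            raise DegenerateInputError(f"constant vector {name!r}")
    rx, ry = _rank(xa), _rank(ya)
    rc = np.column_stack([_rank(c) for c in ctrl]) if k else np.empty((n, 0))
    if k == 0:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    elif method == "inversion":
        corr = np.corrcoef(np.column_stack([rx, ry, rc]), rowvar=False)
        if np.any(np.isnan(corr)):
            raise DegenerateInputError("undefined correlation among ranks")
        rho = _partial_from_corr(corr)
    elif method == "residualization":
        rho = _partial_by_residualization(rx, ry, rc)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.isfinite(rho):
        raise DegenerateInputError("partial correlation undefined (degenerate input)")
    p = _t_p_value(rho, n - 2 - k)
    return CorrelationResult(x_name, y_name, rho, p, n, tuple(control_names))


def multivariate_regression(
    response: Sequence[float],
    predictors: dict[str, Sequence[float]],
    standardize: bool = True,
) -> RegressionResult:
    """OLS of the response on named predictors with per-predictor t-tests.

    ``standardize`` z-scores response and predictors first (default), so
    coefficients are comparable across covariates on different scales; the
    t statistics and p-values are unaffected by the rescaling.
    """
    y = _as_clean_vector(response, "response")
    names = list(predictors)
    cols = [_as_clean_vector(predictors[name], name) for name in names]
    n = y.size
    if any(c.size != n for c in cols):
        raise ValueError("response and predictors must have equal length")
    if n <= len(names) + 1:
        raise ValueError("need n > number of predictors + 1")
    X = np.column_stack(cols)
    if standardize:
        sds = X.std(axis=0, ddof=1)
        if np.any(sds == 0) or y.std(ddof=1) == 0:
            raise DegenerateInputError("constant column under standardization")
        X = (X - X.mean(axis=0)) / sds
        y = (y - y.mean()) / y.std(ddof=1)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateInputError("collinear design matrix")
    fit = sm.OLS(y, design).fit()
    per_pred = tuple(
        PredictorStats(
            name,
            float(fit.params[i + 1]),
            float(fit.bse[i + 1]),
            float(fit.tvalues[i + 1]),
            float(fit.pvalues[i + 1]),
        )
        for i, name in enumerate(names)
    )
    return RegressionResult(per_pred, n, float(fit.rsquared), float(fit.params[0]))


def pca_determinants(
    features: Sequence[Sequence[float]] | np.ndarray,
    variable_names: Optional[Sequence[str]] = None,
) -> PCAResult:
    """PCA of the covariates on the correlation matrix.

    Columns are z-scored, the correlation matrix eigendecomposed, and
    components sorted by descending eigenvalue.  Each component is
    sign-oriented so its largest-magnitude loading is positive; components
    with eigenvalue >= 1 are flagged retained.  Scores are the projections
    of the z-scored rows onto the loadings (PC1 scores feed the downstream
    correlation with evolutionary distance).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix (observations x variables)")
    n, k = X.shape
    if n < 3:
        raise ValueError("need at least 3 complete observations")
    if np.isnan(X).any():
        raise ValueError("features contain NaN; restrict to complete cases first")
    if variable_names is None:
        variable_names = tuple(f"v{i + 1}" for i in range(k))
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [variable_names[i] for i in np.flatnonzero(sds == 0)]
        raise DegenerateInputError(f"constant column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sds
    corr = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    for j in range(k):
        i_max = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i_max, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    scores = Z @ eigvecs
    return PCAResult(
        variable_names=tuple(variable_names),
        eigenvalues=eigvals,
        loadings=eigvecs,
        retained=eigvals >= 1.0,
        scores=scores,
        variance_fractions=eigvals / eigvals.sum(),
    )


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    group_names: tuple[str, str] = ("a", "b"),
) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U comparison of two groups.

    Uses exact enumeration when the pooled sample is small (n1 + n2 <= 12)
    and tie-free, and the tie-corrected normal approximation otherwise.
    """
    aa = _as_clean_vector(a, group_names[0])
    bb = _as_clean_vector(b, group_names[1])
    if aa.size == 0 or bb.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([aa, bb])
    has_ties = np.unique(pooled).size < pooled.size
    if aa.size + bb.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(aa, bb, alternative="two-sided", method=method)
    return GroupComparisonResult(
        group_names,
        (aa.size, bb.size),
        (float(aa.mean()), float(bb.mean())),
        float(res.statistic),
        float(res.pvalue),
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact test p for a 2x2 contingency table.

    p is the sum of hypergeometric probabilities, over tables with the same
    margins, that are no more probable than the observed table.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(p)
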