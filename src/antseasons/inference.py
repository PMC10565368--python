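"""Site-level statistical inference.

Relates per-site responses (activity, variability, component variances,
richness) to the land-cover gradient scores by ordinary least squares with
small-sample AICc model selection over the candidate predictor sets
{}, {PC1}, {PC2}, {PC1, PC2}. Spatial autocorrelation in the residuals of
the selected model is screened with Moran's I under random permutation
(significant autocorrelation would call for a spatially structured model
instead). Paired species-level comparisons between land-cover groups use a
Shapiro-Wilk normality check on the differences followed by the Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import ConfigurationError

logger = logging.getLogger(__name__)

CANDIDATE_SETS: tuple[tuple[str, ...], ...] = ((), ("PC1",), ("PC2",), ("PC1", "PC2"))


def aicc(llf: float, n: int, k: int) -> float:
    """Akaike information criterion with small-sample correction.

    ``k`` counts every estimated parameter including the error variance;
    requires ``n - k - 1 > 0``.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class RegressionResult:
    """AICc model selection outcome for one response."""

    response: str
    selected: tuple[str, ...]
    coefficients: pd.Series
    r_squared: float
    p_values: pd.Series
    aicc_table: pd.Series  # index: candidate label, e.g. "PC1+PC2"
    residuals: np.ndarray

    @property
    def selected_label(self) -> str:
        return "+".join(self.selected) if self.selected else "intercept"


def _label(cand: tuple[str, ...]) -> str:
    return "+".join(cand) if cand else "intercept"


def fit_ols_aicc(
    y: pd.Series | np.ndarray,
    scores: pd.DataFrame,
    response: str = "response",
) -> RegressionResult:
    """Fit all candidate OLS models of ``y`` on PC1/PC2; select by AICc.

    ``scores`` must carry ``PC1`` and ``PC2`` columns aligned with ``y``.
    Candidates whose small-sample correction is undefined (n - k - 1 <= 0)
    are skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 6:
        raise ConfigurationError(f"need >= 6 sites for model selection, got {n}")
    if np.any(np.isnan(y)):
        raise ValueError(f"response {response!r} has missing values")
    if np.var(y) == 0:
        raise ValueError(f"response {response!r} is constant across sites")

    table: dict[str, float] = {}
    fits: dict[str, sm.regression.linear_model.RegressionResultsWrapper] = {}
    for cand in CANDIDATE_SETS:
        X = sm.add_constant(scores[list(cand)].to_numpy()) if cand else np.ones((n, 1))
        k = X.shape[1] + 1  # + error variance
        if n - k - 1 <= 0:
            logger.warning("skipping candidate %s: n - k - 1 <= 0", _label(cand))
            continue
        fit = sm.OLS(y, X).fit()
        table[_label(cand)] = aicc(fit.llf, n, k)
        fits[_label(cand)] = fit

    if not table:
        raise ConfigurationError("no candidate model estimable")
    best = min(table, key=table.get)
    best_cand = next(c for c in CANDIDATE_SETS if _label(c) == best)
    fit = fits[best]
    names = ["intercept", *best_cand]
    return RegressionResult(
        response=response,
        selected=best_cand,
        coefficients=pd.Series(fit.params, index=names),
        r_squared=float(fit.rsquared),
        p_values=pd.Series(fit.pvalues, index=names),
        aicc_table=pd.Series(table),
        residuals=np.asarray(fit.resid),
    )


def fit_ols_simple(y, x) -> tuple[float, float, float]:
    """Slope, its p-value and R^2 of a single-predictor OLS fit."""
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return float(fit.params[1]), float(fit.pvalues[1]), float(fit.rsquared)


# ---------------------------------------------------------------------------
# Moran's I


def spatial_weights(
    coords: np.ndarray, scheme: str = "idw", k: int | None = None
) -> np.ndarray:
    """Row-standardized spatial weights from projected coordinates.

    ``scheme='idw'`` uses inverse Euclidean distance; ``'knn'`` gives equal
    weight to the ``k`` nearest neighbours. Coincident sites get a distance
    floor at the smallest positive pairwise distance (logged).
    """
    xy = np.asarray(coords, dtype=float)
    n = xy.shape[0]
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1))
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        pos = d[off][d[off] > 0]
        if pos.size == 0:
            raise ValueError("all sites coincident: no spatial structure")
        logger.warning("coincident sites: applying minimum-distance floor %.3g", pos.min())
        d[off & (d == 0)] = pos.min()

    if scheme == "idw":
        W = np.zeros((n, n))
        W[off] = 1.0 / d[off]
    elif scheme == "knn":
        if k is None:
            k = min(4, n - 1)
        W = np.zeros((n, n))
        order = np.argsort(d + np.where(off, 0, np.inf), axis=1)
        for i in range(n):
            W[i, order[i, :k]] = 1.0
    else:
        raise ConfigurationError(f"unknown weight scheme {scheme!r}")
    return W / W.sum(axis=1, keepdims=True)


def _morans_i_many(Z: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Moran's I for each row of Z (vectorized over permutations)."""
    Zc = Z - Z.mean(axis=1, keepdims=True)
    n = Z.shape[1]
    s0 = W.sum()
    num = np.einsum("pi,ij,pj->p", Zc, W, Zc)
    den = (Zc**2).sum(axis=1)
    return (n / s0) * num / den


def morans_i(
    residuals: np.ndarray, coords: np.ndarray, weights: str | np.ndarray = "idw"
) -> float:
    """Moran's I spatial autocorrelation statistic of a site vector.

    ``weights`` is a scheme name or a precomputed (n x n) matrix with zero
    diagonal. Raises on zero-variance residuals.
    """
    z = np.asarray(residuals, dtype=float)
    if np.var(z) == 0:
        raise ValueError("zero-variance residuals: Moran's I undefined")
    W = weights if isinstance(weights, np.ndarray) else spatial_weights(coords, weights)
    return float(_morans_i_many(z[None, :], W)[0])


@dataclass(frozen=True)
class SpatialTestResult:
    """Moran's I permutation test report."""

    statistic: float
    p_value: float
    n_perm: int
    expected: float  # -1/(n-1) under the permutation null

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def morans_i_permutation(
    residuals: np.ndarray,
    coords: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    weights: str | np.ndarray = "idw",
) -> SpatialTestResult:
    """Two-sided permutation test of Moran's I.

    Residuals are randomly reassigned to sites ``n_perm`` times; the
    two-sided p-value counts permuted statistics at least as far from the
    null expectation E[I] = -1/(n-1) as the observed one, with the +1
    correction that keeps p in (0, 1].
    """
    if n_perm < 99:
        raise ConfigurationError(f"n_perm must be >= 99, got {n_perm}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = np.asarray(residuals, dtype=float)
    n = z.size
    W = weights if isinstance(weights, np.ndarray) else spatial_weights(coords, weights)
    i_obs = float(_morans_i_many(z[None, :], W)[0])
    perms = rng.permuted(np.broadcast_to(z, (n_perm, n)).copy(), axis=1)
    i_perm = _morans_i_many(perms, W)
    e_i = -1.0 / (n - 1)
    p = (1 + int((np.abs(i_perm - e_i) >= abs(i_obs - e_i)).sum())) / (n_perm + 1)
    return SpatialTestResult(statistic=i_obs, p_value=p, n_perm=n_perm, expected=e_i)


# ---------------------------------------------------------------------------
# Paired nonparametric comparison


@dataclass(frozen=True)
class PairedTestReport:
    """Shapiro-Wilk screen + Wilcoxon signed-rank result for paired values."""

    n_pairs: int
    n_nonzero: int
    shapiro_statistic: float
    shapiro_p: float
    differences_normal: bool
    wilcoxon_statistic: float
    wilcoxon_p: float
    method: str
    median_difference: float


def paired_tests(x_a: np.ndarray, x_b: np.ndarray) -> PairedTestReport:
    """Paired comparison of per-species values between two groups.

    Differences are screened with Shapiro-Wilk (normality flag at p > 0.05);
    the reported test is the two-sided Wilcoxon signed-rank with zero
    differences dropped and mid-ranks for ties — exact null distribution for
    n <= 25 without ties, otherwise normal approximation with continuity
    correction.
    """
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero: test degenerate")
    if nz.size < 5:
        raise ValueError(f"need >= 5 non-zero differences, got {nz.size}")

    sw_stat, sw_p = stats.shapiro(d)
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=True, alternative="two-sided", method=method
    )
    return PairedTestReport(
        n_pairs=int(a.size),
        n_nonzero=int(nz.size),
        shapiro_statistic=float(sw_stat),
        shapiro_p=float(sw_p),
        differences_normal=bool(sw_p > 0.05),
        wilcoxon_statistic=float(res.statistic),
        wilcoxon_p=float(res.pvalue),
        method=method,
        median_difference=float(np.median(d)),
    )
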