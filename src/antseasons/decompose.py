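"""Time-series decomposition into seasonal, trend and remainder components.

A count (or temperature) series sampled at a fixed cadence is regressed by
OLS on a linear trend plus first-order Fourier terms of the annual cycle:

    y(t) = b0 + b1*t + sum_k [ gs_k sin(2*pi*k*t/m) + gc_k cos(2*pi*k*t/m) ] + e(t)

with m periods per year (26 for biweekly sampling) and Fourier order K = 1
by default, i.e. seasonality modelled as a single sine wave — appropriate
for series spanning only a couple of annual cycles. The three additive
components are

* trend: b0 + b1*t (the intercept rides with the trend; constants carry no
  variance so component variances are unaffected),
* seasonal: the Fourier part, periodic with period m,
* remainder: the residual, mean zero at the fitted points.

Component variances — absolute and as shares of their sum — summarize how
much of a community's temporal variability is cyclic, directional or
stochastic. Synchrony of a species set follows Loreau & de Mazancourt:
variance of the community sum over the squared sum of species standard
deviations, 1 for perfectly synchronous and 0 for perfectly compensating
dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .variability import UndefinedMetricError


class FitError(ValueError):
    """Design matrix unusable (too few points or rank-deficient)."""


@dataclass(frozen=True)
class Decomposition:
    """Fitted additive decomposition of one series.

    ``gamma_sin``/``gamma_cos`` hold the Fourier coefficients for orders
    1..K; ``seasonal + trend + remainder`` reproduces the observed series at
    every non-missing t (remainder is NaN where y was missing, while
    seasonal and trend are evaluated everywhere).
    """

    t: np.ndarray
    observed: np.ndarray
    beta0: float
    beta1: float
    gamma_sin: np.ndarray
    gamma_cos: np.ndarray
    m: int
    seasonal: np.ndarray
    trend: np.ndarray
    remainder: np.ndarray

    @property
    def gamma_s(self) -> float:
        """First-order sine coefficient."""
        return float(self.gamma_sin[0])

    @property
    def gamma_c(self) -> float:
        """First-order cosine coefficient."""
        return float(self.gamma_cos[0])

    @property
    def amplitude(self) -> float:
        """First-order seasonal amplitude sqrt(gs^2 + gc^2)."""
        return float(np.hypot(self.gamma_s, self.gamma_c))

    @property
    def fitted(self) -> np.ndarray:
        return self.trend + self.seasonal


def _design(t: np.ndarray, m: int, order: int) -> np.ndarray:
    cols = [np.ones_like(t, dtype=float), t.astype(float)]
    for k in range(1, order + 1):
        w = 2 * np.pi * k * t / m
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols)


def fit_tslm(
    y: np.ndarray,
    m: int = 26,
    t: np.ndarray | None = None,
    order: int = 1,
) -> Decomposition:
    """Fit the trend + Fourier(K=order) linear model to a series.

    ``y`` may contain NaN for missing sampling events; those points are
    excluded from the fit but the trend and seasonal components are still
    evaluated there. Requires >= 5 non-missing points spanning more than one
    annual cycle.
    """
    y = np.asarray(y, dtype=float)
    t = np.arange(1, y.size + 1, dtype=float) if t is None else np.asarray(t, dtype=float)
    ok = ~np.isnan(y)
    n_ok = int(ok.sum())
    n_par = 2 + 2 * order
    if n_ok < max(5, n_par + 1):
        raise FitError(f"need at least {max(5, n_par + 1)} non-missing points, got {n_ok}")
    if t[ok].max() - t[ok].min() < m:
        raise FitError("observed span must exceed one annual cycle")

    X = _design(t, m, order)
    coef, _, rank, _ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    if rank < X.shape[1]:
        raise FitError("rank-deficient design (series too short or gappy)")

    beta0, beta1 = float(coef[0]), float(coef[1])
    gamma_sin = coef[2::2].copy()
    gamma_cos = coef[3::2].copy()
    trend = beta0 + beta1 * t
    seasonal = X[:, 2:] @ coef[2:]
    remainder = y - trend - seasonal  # NaN where y missing
    return Decomposition(
        t=t,
        observed=y,
        beta0=beta0,
        beta1=beta1,
        gamma_sin=gamma_sin,
        gamma_cos=gamma_cos,
        m=int(m),
        seasonal=seasonal,
        trend=trend,
        remainder=remainder,
    )


@dataclass(frozen=True)
class ComponentVariances:
    """Absolute and relative variances of the three components.

    Relative shares are each component's variance over the summed variance;
    they sum to one unless the series is constant, in which case
    ``degenerate`` is set and the relative entries are NaN.
    """

    var_seasonal: float
    var_trend: float
    var_remainder: float
    degenerate: bool

    @property
    def total(self) -> float:
        return self.var_seasonal + self.var_trend + self.var_remainder

    @property
    def relative(self) -> dict[str, float]:
        if self.degenerate:
            return {"seasonal": np.nan, "trend": np.nan, "remainder": np.nan}
        return {
            "seasonal": self.var_seasonal / self.total,
            "trend": self.var_trend / self.total,
            "remainder": self.var_remainder / self.total,
        }


def component_variances(d: Decomposition) -> ComponentVariances:
    """Variances of the fitted components over the non-missing time points,
    plus relative shares.

    Uses the population (1/n) variance: the components are deterministic
    functions evaluated on the full observation window, not a sample from a
    larger population, and a pure sinusoid over whole cycles then has
    variance exactly A^2/2. The relative shares are identical under either
    denominator.
    """
    ok = ~np.isnan(d.observed)
    v_seas = float(np.var(d.seasonal[ok]))
    v_trend = float(np.var(d.trend[ok]))
    v_rem = float(np.var(d.remainder[ok]))
    total = v_seas + v_trend + v_rem
    # scale-aware zero test: a constant series leaves O(eps^2) rounding
    # noise in the component variances
    scale = max(1.0, abs(float(np.mean(d.observed[ok]))))
    return ComponentVariances(
        v_seas, v_trend, v_rem, degenerate=(total <= (1e-12 * scale) ** 2)
    )


def loreau_synchrony(X: np.ndarray) -> float:
    """Loreau-de Mazancourt community synchrony.

    ``X`` is species x time. Returns
    ``var(sum_i x_i) / (sum_i sd(x_i))^2``, in [0, 1]. Raises
    ``UndefinedMetricError`` if no species has temporal variance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise UndefinedMetricError("synchrony needs >= 2 species series")
    sds = X.std(axis=1, ddof=1)
    denom = sds.sum() ** 2
    if denom == 0:
        raise UndefinedMetricError("all species series constant: synchrony undefined")
    return float(np.var(X.sum(axis=0), ddof=1) / denom)


def standardize_seasonal(d: Decomposition, total: float) -> np.ndarray:
    """Seasonal component scaled by the species' total activity, making
    curves comparable across species of different abundance."""
    if total <= 0:
        raise ValueError("total activity must be positive")
    return d.seasonal / float(total)


def mean_seasonal_curve(curves: np.ndarray) -> np.ndarray:
    """Average standardized seasonal curve over species (rows)."""
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    return curves.mean(axis=0)
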