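"""Temporal variability and richness metrics per site.

Two complementary facets of community variability over time:

* functional — the coefficient of variation of the community-total count
  series, approximating variability of aggregate ecosystem activity;
* compositional — temporal beta diversity, the total variance of the
  Hellinger-transformed species-by-time matrix, with per-species
  contributions (SCBD) that sum to one.

Richness summaries (observed, rarefied, and Chao-style extrapolated Hill
q=0) quantify whether richness differences could confound the variability
patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity import rarefy_matrix

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (e.g. zero-mean series)."""


def functional_cv(totals: np.ndarray) -> float:
    """Coefficient of variation (sample SD / mean) of a total-count series."""
    y = np.asarray(totals, dtype=float)
    y = y[~np.isnan(y)]
    if y.size < 2:
        raise UndefinedMetricError("CV needs at least 2 time points")
    mean = y.mean()
    if mean <= 0:
        raise UndefinedMetricError("CV undefined for non-positive mean")
    return float(y.std(ddof=1) / mean)


def hellinger(matrix_t: np.ndarray) -> np.ndarray:
    """Hellinger-transform a (time x species) matrix: sqrt of row-relative
    abundances. Rows with zero total must be removed beforehand."""
    Y = np.asarray(matrix_t, dtype=float)
    row_tot = Y.sum(axis=1, keepdims=True)
    return np.sqrt(Y / row_tot)


def temporal_beta_diversity(matrix: np.ndarray) -> tuple[float, np.ndarray]:
    """Total temporal beta diversity and species contributions (SCBD).

    ``matrix`` is species x time. Time steps (columns) with zero total are
    dropped with a warning. The time-step rows are Hellinger-transformed,
    columns centred, and the total sum of squares scaled by (T - 1):
    ``BD_total = SS_total / (T - 1)``; ``SCBD_j = SS_j / SS_total``.

    Returns ``(bd_total, scbd)`` with ``scbd`` summing to 1 (or an all-NaN
    vector if the composition never changes, in which case BD_total = 0).
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise UndefinedMetricError("need a species x time matrix with >= 2 time steps")
    col_tot = M.sum(axis=0)
    keep = col_tot > 0
    if not keep.all():
        logger.warning("dropping %d time steps with zero total count", int((~keep).sum()))
    M = M[:, keep]
    if M.shape[1] < 2:
        raise UndefinedMetricError("fewer than 2 time steps with nonzero totals")

    Y = hellinger(M.T)  # time x species
    dev = Y - Y.mean(axis=0, keepdims=True)
    ss_species = (dev**2).sum(axis=0)
    ss_total = ss_species.sum()
    bd_total = float(ss_total / (Y.shape[0] - 1))
    if ss_total == 0:
        return 0.0, np.full(M.shape[0], np.nan)
    return bd_total, ss_species / ss_total


def hill_q0_extrapolated(abundances: np.ndarray) -> float:
    """Chao-style extrapolated species richness (Hill number, q = 0).

    Uses singleton (f1) and doubleton (f2) counts to estimate the number of
    undetected species ``f0_hat`` and extrapolates the accumulation curve to
    double the observed sample size (endpoint m* = n)::

        f0_hat = ((n-1)/n) * f1^2 / (2 f2)            if f2 > 0
               = ((n-1)/n) * f1 (f1-1) / 2            if f2 = 0
        S(2n)  = S_obs + f0_hat * [1 - (1 - f1 / (n f0_hat + f1))^n]
    """
    x = np.asarray(abundances)
    x = x[x > 0]
    if x.size == 0:
        raise UndefinedMetricError("no individuals: richness undefined")
    n = int(x.sum())
    s_obs = int(x.size)
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return float(s_obs)
    if f2 > 0:
        f0_hat = (n - 1) / n * f1**2 / (2 * f2)
    else:
        f0_hat = (n - 1) / n * f1 * (f1 - 1) / 2
    if f0_hat == 0:
        return float(s_obs)
    m_star = n
    return float(s_obs + f0_hat * (1 - (1 - f1 / (n * f0_hat + f1)) ** m_star))


def richness_summary(
    matrix: np.ndarray,
    target: int | None = None,
    n_rep: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Observed, rarefied and extrapolated richness for one count matrix.

    ``observed`` counts species with >= 1 individual; ``rarefied`` is the
    mean observed richness over ``n_rep`` individual-based rarefactions to
    ``target`` (skipped if ``target`` is None); ``extrapolated`` is the
    Hill q=0 estimate from site-level abundance frequency counts.
    """
    M = np.asarray(matrix)
    if M.size == 0:
        raise UndefinedMetricError("empty matrix")
    abund = M.sum(axis=-1) if M.ndim == 2 else M
    observed = float((abund > 0).sum())
    out = {
        "observed": observed,
        "extrapolated": hill_q0_extrapolated(abund),
    }
    if target is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        reps = rarefy_matrix(np.atleast_2d(M), int(target), n_rep, rng)
        rich = (reps.sum(axis=-1) > 0).sum(axis=-1)
        out["rarefied"] = float(rich.mean())
    return out


@dataclass(frozen=True)
class VariabilityResult:
    """Per-site variability and richness summary (one rarefied replicate or
    a replicate average)."""

    unit: str
    cv: float
    bd_total: float
    scbd: pd.Series  # index: species, sums to 1
    richness: dict[str, float]

    def scbd_by_status(self, status_map: pd.Series) -> pd.Series:
        """Sum SCBD over species status categories (sums preserve total)."""
        return self.scbd.groupby(self.scbd.index.map(status_map)).sum()


def site_variability(
    matrix: np.ndarray,
    species: np.ndarray,
    unit: str = "",
    target: int | None = None,
    n_rep: int = 100,
    seed: int | np.random.Generator = 0,
) -> VariabilityResult:
    """Compute all variability metrics for one species x time matrix."""
    bd, scbd = temporal_beta_diversity(matrix)
    return VariabilityResult(
        unit=unit,
        cv=functional_cv(np.asarray(matrix).sum(axis=0)),
        bd_total=bd,
        scbd=pd.Series(scbd, index=pd.Index(species, name="species")),
        richness=richness_summary(matrix, target=target, n_rep=n_rep, seed=seed),
    )
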