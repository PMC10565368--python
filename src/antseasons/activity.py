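"""Count-data conditioning: thresholding, aggregation, rarefaction.

The raw unit of observation is a station-level trap count per species per
biweekly period. Extreme outliers (mass recruitment events near a trap) are
capped at a threshold before anything else; station counts are then summed
to site level (and site counts to land-cover-group level); finally sites
are rarefied — individuals subsampled without replacement down to a common
total — to remove mean-variance sampling artefacts before variability
metrics are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import ConfigurationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("site", "station", "species", "period", "count")


class InfeasibleTargetError(ValueError):
    """Rarefaction target exceeds the available individuals."""


@dataclass(frozen=True)
class SiteSeries:
    """Species-by-time count matrix for one site (or site group).

    ``matrix`` has shape (n_species, n_periods); column sums give the
    community-total series. ``periods`` is the common 1..T index.
    """

    unit: str
    species: np.ndarray
    periods: np.ndarray
    matrix: np.ndarray

    @property
    def totals(self) -> np.ndarray:
        """Community-total activity per period (all species summed)."""
        return self.matrix.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.matrix.sum())

    def species_series(self, species: str) -> np.ndarray:
        i = np.flatnonzero(self.species == species)
        if len(i) == 0:
            raise KeyError(f"species {species!r} not in series for {self.unit!r}")
        return self.matrix[i[0]]


def validate_table(table: pd.DataFrame) -> None:
    """Check the long-format activity table contract."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"activity table missing columns: {missing}")
    counts = table["count"]
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, counts.round()):
            raise ValueError("counts must be integers")
    if table.duplicated(subset=["site", "station", "species", "period"]).any():
        raise ValueError("(site, station, species, period) keys must be unique")


def apply_threshold(table: pd.DataFrame, cap: int = 500) -> pd.DataFrame:
    """Cap station-level counts at ``cap``; everything else is untouched.

    Applied before any aggregation: the cap targets single-trap recruitment
    outliers, which summation would otherwise smear into site totals.
    """
    if cap < 1:
        raise ConfigurationError(f"threshold cap must be >= 1, got {cap}")
    out = table.copy()
    n_capped = int((out["count"] > cap).sum())
    if n_capped:
        logger.info("thresholding capped %d counts at %d", n_capped, cap)
    out["count"] = out["count"].clip(upper=cap)
    return out


def aggregate(
    table: pd.DataFrame,
    level: str = "site",
    group_map: dict[str, str] | None = None,
) -> dict[str, SiteSeries]:
    """Sum station counts to site level, or site counts to group level.

    Returns one ``SiteSeries`` per unit, all sharing the same species order
    and the full 1..max(period) time index (missing cells contribute 0, with
    a warning if whole stations are absent).

    ``level='group'`` requires ``group_map`` (site -> group); sites mapped
    to ``None`` are dropped; sites absent from the map raise ``KeyError``.
    """
    validate_table(table)
    work = table
    if level == "site":
        keys = work["site"]
    elif level == "group":
        if group_map is None:
            raise ConfigurationError("group aggregation requires group_map")
        unknown = set(work["site"].unique()) - set(group_map)
        if unknown:
            raise KeyError(f"sites missing from group_map: {sorted(unknown)}")
        keys = work["site"].map(group_map)
        work = work[keys.notna()]
        keys = keys[keys.notna()]
    else:
        raise ConfigurationError(f"unknown aggregation level {level!r}")

    n_station_sets = table.groupby("site")["station"].nunique()
    if n_station_sets.nunique() > 1:
        logger.warning(
            "sites have unequal station counts (%s); missing stations contribute 0",
            dict(n_station_sets),
        )

    periods = np.arange(1, int(table["period"].max()) + 1)
    species = np.sort(table["species"].unique())
    summed = (
        work.assign(_unit=keys.to_numpy())
        .groupby(["_unit", "species", "period"], sort=True)["count"]
        .sum()
    )
    out: dict[str, SiteSeries] = {}
    for unit, sub in summed.groupby(level="_unit"):
        mat = (
            sub.droplevel("_unit")
            .unstack("period", fill_value=0)
            .reindex(index=species, columns=periods, fill_value=0)
        )
        out[str(unit)] = SiteSeries(
            unit=str(unit),
            species=species,
            periods=periods,
            matrix=mat.to_numpy(dtype=np.int64),
        )
    return out


def rarefy_matrix(
    matrix: np.ndarray, target: int, n_rep: int, rng: np.random.Generator
) -> np.ndarray:
    """Rarefy a count matrix: ``n_rep`` draws of ``target`` individuals
    without replacement from the pooled cells (multivariate hypergeometric).

    Returns an (n_rep, *matrix.shape) integer array; each replicate's grand
    total is exactly ``target`` and each cell's expectation is
    ``cell * target / total``.
    """
    flat = np.asarray(matrix, dtype=np.int64).ravel()
    total = int(flat.sum())
    if target > total:
        raise InfeasibleTargetError(f"target {target} exceeds total {total}")
    if target == total:
        return np.broadcast_to(flat, (n_rep, flat.size)).reshape((n_rep, *matrix.shape)).copy()
    draws = rng.multivariate_hypergeometric(flat, target, size=n_rep)
    return draws.reshape((n_rep, *matrix.shape))


def rarefy(
    series: SiteSeries, target: int, n_rep: int = 100, seed: int | np.random.Generator = 0
) -> list[SiteSeries]:
    """Rarefy one site's species-by-time matrix to ``target`` individuals.

    Pools over all (species, period) cells — the two-year total is equalized,
    preserving the joint species-time structure in expectation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = rarefy_matrix(series.matrix, target, n_rep, rng)
    return [replace(series, matrix=reps[r]) for r in range(n_rep)]


def rarefy_species_between_groups(
    series_a: np.ndarray,
    series_b: np.ndarray,
    n_rep: int = 100,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rarefy one species' two group-level time series to their common
    minimum total, for balanced between-group comparisons.

    Returns two (n_rep, T) arrays. The group already at the minimum is
    passed through unchanged (every replicate identical).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(series_a, dtype=np.int64)
    b = np.asarray(series_b, dtype=np.int64)
    if a.sum() == 0 or b.sum() == 0:
        raise InfeasibleTargetError("species absent from a group; filter upstream")
    target = int(min(a.sum(), b.sum()))
    reps_a = rarefy_matrix(a, target, n_rep, rng)
    reps_b = rarefy_matrix(b, target, n_rep, rng)
    return reps_a, reps_b


def read_activity(path) -> pd.DataFrame:
    """Read a long-format activity CSV and validate it."""
    table = pd.read_csv(path)
    validate_table(table)
    return table


def write_activity(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
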