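"""Configuration objects and flat key:value config file I/O."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

logging.basicConfig(
    level=logging.INFO,
    format="%(asctime)s %(levelname)s %(name)s: %(message)s",
)


class ConfigurationError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic monitoring study.

    Defaults emulate a biweekly trap survey: 24 sites with 3 trap stations
    each, sampled over 52 consecutive 2-week periods (2 years at 26 periods
    per year), with a regional species pool whose seasonal amplitude covaries
    with forest cover.

    Parameters
    ----------
    n_sites, n_stations, n_periods, period_per_year
        Survey design. ``n_periods`` must be a whole number of years.
    n_species
        Size of the regional species pool.
    seed
        Seed for all random draws; identical configs + seed reproduce
        bit-identical tables.
    seasonal_gain
        Coefficient linking site forest proportion to per-species
        log-amplitude of the seasonal (sine) forcing. 0 decouples
        seasonality from land cover.
    baseline_gain
        Coefficient linking forest proportion to per-species baseline
        log-rate. Negative values make developed sites more active overall,
        as passive trap surveys of disturbed habitats typically find.
    affinity_gain
        Optional composition-turnover scenario: log-rate bonus each species
        gets toward its preferred habitat (forest-affiliated species rarer
        at developed sites and vice versa). Off (0) by default because
        turnover interacts with the phase structure and would confound the
        ``seasonal_gain = 0`` null.
    trend_sd
        Standard deviation of per-species log-linear drift per period.
    dispersion
        Negative-binomial size parameter for count noise
        (``var = mu + mu^2/dispersion``); ``inf`` gives Poisson counts.
    status_probs
        Probabilities that a species is native / alien / uncertain.
    forest_gradient
        If True, forest proportion increases south to north
        (with the y coordinate); if False, landscape is spatially random.
    """

    n_sites: int = 24
    n_stations: int = 3
    n_periods: int = 52
    period_per_year: int = 26
    n_species: int = 40
    seed: int = 0
    seasonal_gain: float = 1.5
    baseline_gain: float = -1.0
    affinity_gain: float = 0.0
    trend_sd: float = 0.004
    dispersion: float = 5.0
    status_probs: tuple[float, float, float] = (0.5, 0.2, 0.3)
    forest_gradient: bool = True

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_stations", "n_periods", "period_per_year", "n_species"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_periods % self.period_per_year != 0:
            raise ConfigurationError(
                f"n_periods ({self.n_periods}) must be a multiple of "
                f"period_per_year ({self.period_per_year})"
            )
        if abs(sum(self.status_probs) - 1.0) > 1e-9:
            raise ConfigurationError(f"status_probs must sum to 1, got {self.status_probs}")
        if any(p < 0 for p in self.status_probs):
            raise ConfigurationError("status_probs must be non-negative")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive (inf for Poisson)")
        if self.trend_sd < 0:
            raise ConfigurationError("trend_sd must be >= 0")

    @property
    def n_years(self) -> int:
        return self.n_periods // self.period_per_year

    def to_file(self, path: str | Path) -> None:
        """Write the config as flat ``key: value`` lines."""
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(repr(x) for x in v)
            lines.append(f"{f.name}: {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition(":")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ConfigurationError(f"unknown config key {key!r}")
            if key == "status_probs":
                kwargs[key] = tuple(float(x) for x in raw.split(","))
            elif key == "forest_gradient":
                kwargs[key] = raw.lower() in ("true", "1", "yes")
            elif key in ("seasonal_gain", "baseline_gain", "affinity_gain", "trend_sd", "dispersion"):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = int(raw)
        return cls(**kwargs)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


#: Land-cover classes, in fixed column order.
LANDCOVER_CLASSES = (
    "forest",
    "agriculture",
    "urban",
    "grass",
    "sand",
    "freshwater",
    "miscellaneous",
)

#: Species status labels.
STATUSES = ("native", "alien", "uncertain")


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the analysis pipeline itself (as opposed to the data).

    ``threshold`` caps extreme station-level counts before any aggregation;
    ``n_rarefaction_reps`` controls how many rarefied datasets metrics are
    averaged over; ``min_total`` is the combined-count filter for the
    between-group species comparison (strict ``>`` by default, set
    ``min_total_inclusive`` for ``>=``).
    """

    threshold: int = 500
    n_rarefaction_reps: int = 100
    n_per_group: int = 8
    min_total: int = 100
    min_total_inclusive: bool = False
    n_permutations: int = 999
    fourier_order: int = 1

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ConfigurationError("threshold must be >= 1")
        if self.n_rarefaction_reps < 1:
            raise ConfigurationError("n_rarefaction_reps must be >= 1")
        if self.n_permutations < 99:
            raise ConfigurationError("n_permutations must be >= 99")
        if self.fourier_order < 1:
            raise ConfigurationError("fourier_order must be >= 1")
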