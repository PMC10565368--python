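"""Synthetic monitoring-study generator.

Produces landscapes, species pools and negative-binomial count time series
with the statistical structure the downstream analysis assumes: a forest
cover gradient across sites, per-species sinusoidal seasonal forcing whose
log-amplitude covaries with forest cover, log-linear drift, and overdispersed
station-level counts that sum losslessly to site level. Every quantity the
pipeline later estimates (seasonal amplitude, trend, phase, baseline rate)
exists here as ground truth, so recovery can be tested end to end.

The generative model (none is prescribed by the field protocol this
emulates; all choices are documented stand-ins, see docs/methods.md):

* site ``s`` has forest proportion ``f_s`` spanning [0.05, 0.95];
* species ``i`` at site ``s`` has log-mean activity at period ``t``::

      mu_ist = b_is + A_is * sin(2*pi*t/m + phi_i) + beta_i * t

  with ``b_is = b_i + baseline_gain*(f_s - mean f)`` and
  ``log A_is = a_i + seasonal_gain*(f_s - mean f)``;
* the site-level count is negative-binomial with mean ``exp(mu_ist)`` and
  size ``dispersion`` (Poisson in the ``dispersion -> inf`` limit), then
  split multinomially over the site's stations, so station-to-site
  summation is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import LANDCOVER_CLASSES, STATUSES, ConfigurationError, SimulationConfig

logger = logging.getLogger(__name__)

# Fixed per-operation RNG stream keys so each generator stage is
# independently reproducible from the config seed alone.
_STREAM_LANDSCAPE = 11
_STREAM_POOL = 23
_STREAM_COUNTS = 37

# Species-pool hyperparameters (log scale): chosen so per-cell counts span
# roughly 0-50 per biweekly period with a handful of dominant species, the
# regime passive trap surveys of ground-foraging insects operate in.
_BASELINE_LOGMEAN = np.log(0.5)
_BASELINE_LOGSD = 2.0
_LOGAMP_MEAN = np.log(0.6)
_LOGAMP_SD = 0.4
_PHASE_KAPPA = 8.0  # von Mises concentration for forest-affiliated species
_FOREST_AFFINITY = {"native": 0.8, "alien": 0.2, "uncertain": 0.5}


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


@dataclass(frozen=True)
class GroundTruth:
    """True generative parameters behind one simulated dataset.

    ``baseline`` and ``amplitude`` are (n_species, n_sites) arrays on the
    log-mean scale; ``phase`` (radians, in [0, 2pi)) and ``trend_slope``
    (per period) are per species; ``forest`` is the per-site forest
    proportion in the same site order.
    """

    species: np.ndarray
    sites: np.ndarray
    status: np.ndarray
    baseline: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    trend_slope: np.ndarray
    forest: np.ndarray

    def __post_init__(self) -> None:
        assert np.all(self.amplitude >= 0)
        assert np.all((self.phase >= 0) & (self.phase < 2 * np.pi))

    def to_frame(self) -> pd.DataFrame:
        """Long-format (species, site) table of the generative parameters."""
        ns, nk = len(self.species), len(self.sites)
        return pd.DataFrame(
            {
                "species": np.repeat(self.species, nk),
                "site": np.tile(self.sites, ns),
                "status": np.repeat(self.status, nk),
                "baseline": self.baseline.ravel(),
                "amplitude": self.amplitude.ravel(),
                "phase": np.repeat(self.phase, nk),
                "trend_slope": np.repeat(self.trend_slope, nk),
                "forest": np.tile(self.forest, ns),
            }
        )


def generate_landscape(cfg: SimulationConfig) -> pd.DataFrame:
    """Generate per-site coordinates and land-cover proportions.

    Returns a site metadata table with columns ``site``, ``x``, ``y``
    (metres, projected plane) and the seven land-cover proportions, each row
    summing to one. Forest proportions are evenly spread over [0.05, 0.95]
    so the gradient always spans nearly the full range; the remaining mass
    is shared among the other six classes with agriculture and urban
    dominating, so that developed sites mirror forested ones. With
    ``cfg.forest_gradient`` the forest proportion increases south to north
    (with y); otherwise forest is spatially random.
    """
    rng = _rng(cfg, _STREAM_LANDSCAPE)
    n = cfg.n_sites
    forest = np.linspace(0.05, 0.95, n) if n > 1 else np.array([0.5])

    # Split the non-forest mass among the 6 remaining classes.
    alphas = np.array([3.0, 3.0, 1.5, 0.5, 0.5, 0.5])  # agri, urban, grass, sand, fresh, misc
    rest = rng.dirichlet(alphas, size=n) * (1.0 - forest)[:, None]
    props = np.column_stack([forest, rest])

    x = rng.uniform(0.0, 30_000.0, size=n)
    y = rng.uniform(0.0, 100_000.0, size=n)
    if cfg.forest_gradient:
        # south-north gradient: most-forested sites sit at high y
        y = np.sort(y)  # forest already ascending
    sites = np.array([f"S{i + 1:02d}" for i in range(n)])

    meta = pd.DataFrame({"site": sites, "x": x, "y": y})
    for j, cls in enumerate(LANDCOVER_CLASSES):
        meta[cls] = props[:, j]
    return meta


def generate_species_pool(
    cfg: SimulationConfig, meta: pd.DataFrame
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a species pool with statuses and generative parameters.

    Returns ``(status_table, ground_truth)``. Statuses follow
    ``cfg.status_probs``. Forest-affiliated species (natives mostly) share a
    concentrated von Mises phase, giving synchronous seasonality in forest;
    developed-affiliated species get uniform phases, so their seasonal peaks
    are mismatched. ``seasonal_gain`` scales log-amplitude with site forest
    cover; 0 makes amplitude independent of land cover.
    """
    rng = _rng(cfg, _STREAM_POOL)
    n_sp, n_sites = cfg.n_species, len(meta)
    species = np.array([f"sp{i + 1:03d}" for i in range(n_sp)])
    status = rng.choice(STATUSES, size=n_sp, p=np.asarray(cfg.status_probs, dtype=float))

    forest = meta["forest"].to_numpy(dtype=float)
    f_centred = forest - forest.mean()

    affinity_p = np.array([_FOREST_AFFINITY[s] for s in status])
    forest_affiliated = rng.random(n_sp) < affinity_p

    # baseline log-rate: species-level abundance spread, a community-wide
    # development effect (baseline_gain), and an optional habitat-affinity
    # effect (affinity_gain) that makes species rarer away from their
    # preferred land cover. The affinity effect is a scenario knob, off by
    # default: composition turnover along the gradient interacts with the
    # phase structure and would confound the seasonal_gain=0 null.
    b_i = rng.normal(_BASELINE_LOGMEAN, _BASELINE_LOGSD, size=n_sp)
    affinity_sign = np.where(forest_affiliated, 1.0, -1.0)
    baseline = (
        b_i[:, None]
        + cfg.baseline_gain * f_centred[None, :]
        + cfg.affinity_gain * affinity_sign[:, None] * f_centred[None, :]
    )

    a_i = rng.normal(_LOGAMP_MEAN, _LOGAMP_SD, size=n_sp)
    amplitude = np.exp(a_i[:, None] + cfg.seasonal_gain * f_centred[None, :])
    phase = np.where(
        forest_affiliated,
        rng.vonmises(0.0, _PHASE_KAPPA, size=n_sp),
        rng.uniform(-np.pi, np.pi, size=n_sp),
    )
    phase = np.mod(phase, 2 * np.pi)

    trend_slope = rng.normal(0.0, cfg.trend_sd, size=n_sp)

    status_table = pd.DataFrame({"species": species, "status": status})
    truth = GroundTruth(
        species=species,
        sites=meta["site"].to_numpy(),
        status=status,
        baseline=baseline,
        amplitude=amplitude,
        phase=phase,
        trend_slope=trend_slope,
        forest=forest,
    )
    return status_table, truth


def simulate_counts(
    meta: pd.DataFrame, truth: GroundTruth, cfg: SimulationConfig
) -> pd.DataFrame:
    """Simulate the long-format activity table.

    One row per (site, station, species, period) including explicit zeros.
    Site-level counts are negative-binomial around the log-link mean and
    split multinomially over stations with per-site Dirichlet weights, so
    summing stations recovers the site-level draw exactly.
    """
    if not np.array_equal(meta["site"].to_numpy(), truth.sites):
        raise KeyError("site ids in metadata do not match ground truth")
    rng = _rng(cfg, _STREAM_COUNTS)
    n_sp, n_sites = len(truth.species), len(truth.sites)
    T, m = cfg.n_periods, cfg.period_per_year
    t = np.arange(1, T + 1, dtype=float)

    seasonal = truth.amplitude[:, :, None] * np.sin(
        2 * np.pi * t[None, None, :] / m + truth.phase[:, None, None]
    )
    mu = truth.baseline[:, :, None] + seasonal + truth.trend_slope[:, None, None] * t
    lam = np.exp(mu)  # (n_sp, n_sites, T)

    if np.isinf(cfg.dispersion):
        site_counts = rng.poisson(lam)
    else:
        k = float(cfg.dispersion)
        site_counts = rng.negative_binomial(k, k / (k + lam))

    station_w = rng.dirichlet(np.full(cfg.n_stations, 8.0), size=n_sites)
    # split each site's draw over its stations; loop over sites so each
    # multinomial uses that site's weight vector
    station_counts = np.empty((n_sp, n_sites, T, cfg.n_stations), dtype=np.int64)
    for s in range(n_sites):
        station_counts[:, s] = rng.multinomial(site_counts[:, s], station_w[s])

    stations = np.array([f"st{j + 1}" for j in range(cfg.n_stations)])
    idx = pd.MultiIndex.from_product(
        [truth.species, truth.sites, np.arange(1, T + 1), stations],
        names=["species", "site", "period", "station"],
    )
    table = pd.DataFrame({"count": station_counts.ravel()}, index=idx).reset_index()
    return table[["site", "station", "species", "period", "count"]]


def simulate_temperature(
    meta: pd.DataFrame, cfg: SimulationConfig, amplitude: float = 8.0, noise_sd: float = 1.0
) -> pd.DataFrame:
    """Optional site temperature series: annual sine + white noise.

    Emulates sensor data for exercising the decomposition on a non-count
    series; the seasonal amplitude is deliberately identical across sites
    (the null the field comparison tests against).
    """
    rng = _rng(cfg, _STREAM_COUNTS + 1)
    T, m = cfg.n_periods, cfg.period_per_year
    t = np.arange(1, T + 1)
    rows = []
    for site in meta["site"]:
        base = 22.0 + amplitude * np.sin(2 * np.pi * t / m - np.pi / 2)
        air = base + rng.normal(0, noise_sd, T)
        soil = base * 0.8 + 4.0 + rng.normal(0, noise_sd * 0.5, T)
        rows.append(pd.DataFrame({"site": site, "period": t, "air_temp": air, "soil_temp": soil}))
    return pd.concat(rows, ignore_index=True)


def write_dataset(
    outdir: str | Path,
    cfg: SimulationConfig,
    meta: pd.DataFrame,
    status_table: pd.DataFrame,
    truth: GroundTruth,
    table: pd.DataFrame,
) -> None:
    """Write all simulated tables plus the config to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta.to_csv(out / "site_metadata.csv", index=False)
    status_table.to_csv(out / "species_status.csv", index=False)
    truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
    table.to_csv(out / "activity.csv", index=False)
    cfg.to_file(out / "config.txt")
    logger.info("wrote simulated dataset to %s", out)


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth, pd.DataFrame]:
    """Convenience wrapper: landscape -> pool -> counts.

    Returns ``(meta, status_table, truth, activity_table)``.
    """
    meta = generate_landscape(cfg)
    status_table, truth = generate_species_pool(cfg, meta)
    table = simulate_counts(meta, truth, cfg)
    return meta, status_table, truth, table
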