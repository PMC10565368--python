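"""Generator contracts: simplex landscapes, gradient coupling, count law."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import antseasons as ans
from antseasons.config import LANDCOVER_CLASSES


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ans.ConfigurationError):
            ans.SimulationConfig(n_sites=0)
        with pytest.raises(ans.ConfigurationError):
            ans.SimulationConfig(n_periods=50)  # not a multiple of 26
        with pytest.raises(ans.ConfigurationError):
            ans.SimulationConfig(status_probs=(0.5, 0.5, 0.5))
        with pytest.raises(ans.ConfigurationError):
            ans.SimulationConfig(dispersion=0)

    def test_config_file_roundtrip(self, tmp_path):
        cfg = ans.SimulationConfig(n_sites=10, seed=42, seasonal_gain=0.7,
                                   status_probs=(0.2, 0.3, 0.5))
        cfg.to_file(tmp_path / "cfg.txt")
        assert ans.SimulationConfig.from_file(tmp_path / "cfg.txt") == cfg


class TestLandscape:
    def test_proportions_on_simplex(self):
        meta = ans.generate_landscape(ans.SimulationConfig(n_sites=24, seed=1))
        assert len(meta) == 24
        sums = meta[list(LANDCOVER_CLASSES)].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert (meta[list(LANDCOVER_CLASSES)] >= 0).all().all()

    def test_forest_spans_gradient(self):
        meta = ans.generate_landscape(ans.SimulationConfig(n_sites=24, seed=3))
        assert meta["forest"].min() <= 0.1
        assert meta["forest"].max() >= 0.9

    def test_deterministic_under_seed(self):
        cfg = ans.SimulationConfig(seed=9)
        pd.testing.assert_frame_equal(
            ans.generate_landscape(cfg), ans.generate_landscape(cfg)
        )

    def test_gradient_couples_forest_to_latitude(self):
        meta = ans.generate_landscape(ans.SimulationConfig(n_sites=24, seed=2))
        assert np.corrcoef(meta["forest"], meta["y"])[0, 1] > 0.9

    def test_gradient_disabled_is_spatially_null(self):
        # Monte-Carlo: mean correlation over 200 seeds ~ N(0, SE)
        corrs = []
        for seed in range(200):
            cfg = ans.SimulationConfig(n_sites=24, seed=seed, forest_gradient=False)
            meta = ans.generate_landscape(cfg)
            corrs.append(np.corrcoef(meta["forest"], meta["y"])[0, 1])
        se = np.std(corrs, ddof=1) / np.sqrt(len(corrs))
        assert abs(np.mean(corrs)) < 3 * se + 1e-3


class TestSpeciesPool:
    def test_statuses_and_parameter_shapes(self, small_cfg):
        meta = ans.generate_landscape(small_cfg)
        status, truth = ans.generate_species_pool(small_cfg, meta)
        assert set(status["status"]) <= set(ans.STATUSES)
        assert truth.amplitude.shape == (small_cfg.n_species, small_cfg.n_sites)
        assert np.all(truth.amplitude >= 0)
        assert np.all((truth.phase >= 0) & (truth.phase < 2 * np.pi))

    def test_degenerate_status_probs(self):
        cfg = ans.SimulationConfig(n_sites=5, n_species=30, seed=4,
                                   status_probs=(1.0, 0.0, 0.0))
        meta = ans.generate_landscape(cfg)
        status, _ = ans.generate_species_pool(cfg, meta)
        assert (status["status"] == "native").all()

    def test_amplitude_tracks_forest_when_gain_positive(self):
        hits = 0
        for seed in range(100):
            cfg = ans.SimulationConfig(n_sites=12, n_species=20, seed=seed,
                                       seasonal_gain=2.0)
            meta = ans.generate_landscape(cfg)
            _, truth = ans.generate_species_pool(cfg, meta)
            rho = stats.spearmanr(truth.amplitude.mean(axis=0), truth.forest).statistic
            hits += rho > 0
        assert hits >= 95

    def test_amplitude_independent_of_forest_when_gain_zero(self):
        slopes = []
        for seed in range(100):
            cfg = ans.SimulationConfig(n_sites=12, n_species=20, seed=seed,
                                       seasonal_gain=0.0)
            meta = ans.generate_landscape(cfg)
            _, truth = ans.generate_species_pool(cfg, meta)
            # per-species amplitude is exactly constant across sites
            slopes.append(np.ptp(truth.amplitude, axis=1).max())
        assert np.max(slopes) < 1e-12


class TestCounts:
    def test_deterministic_under_seed(self, small_cfg):
        t1 = ans.simulate_dataset(small_cfg)[3]
        t2 = ans.simulate_dataset(small_cfg)[3]
        pd.testing.assert_frame_equal(t1, t2)

    def test_poisson_limit_matches_log_link_mean(self):
        # dispersion -> inf, A = 0, slope = 0: site-level cells ~ Poisson(e^b)
        cfg = ans.SimulationConfig(
            n_sites=2, n_stations=3, n_periods=52 * 2, period_per_year=26,
            n_species=50, seed=21, dispersion=np.inf,
        )
        meta = ans.generate_landscape(cfg)
        n_sp, n_sites = cfg.n_species, cfg.n_sites
        b = np.log(5.0)
        truth = ans.GroundTruth(
            species=np.array([f"sp{i:03d}" for i in range(n_sp)]),
            sites=meta["site"].to_numpy(),
            status=np.array(["native"] * n_sp),
            baseline=np.full((n_sp, n_sites), b),
            amplitude=np.zeros((n_sp, n_sites)),
            phase=np.zeros(n_sp),
            trend_slope=np.zeros(n_sp),
            forest=meta["forest"].to_numpy(),
        )
        table = ans.simulate_counts(meta, truth, cfg)
        site_cells = table.groupby(["site", "species", "period"])["count"].sum()
        n_cells = len(site_cells)  # 2 * 50 * 104 = 10400
        assert n_cells >= 10_000
        se = np.sqrt(5.0 / n_cells)
        assert abs(site_cells.mean() - 5.0) < 3 * se

    def test_negative_binomial_keeps_log_link_mean(self):
        cfg = ans.SimulationConfig(n_sites=2, n_periods=104, n_species=50,
                                   seed=22, dispersion=2.0)
        meta = ans.generate_landscape(cfg)
        n_sp = cfg.n_species
        truth = ans.GroundTruth(
            species=np.array([f"sp{i:03d}" for i in range(n_sp)]),
            sites=meta["site"].to_numpy(),
            status=np.array(["native"] * n_sp),
            baseline=np.full((n_sp, 2), np.log(5.0)),
            amplitude=np.zeros((n_sp, 2)),
            phase=np.zeros(n_sp),
            trend_slope=np.zeros(n_sp),
            forest=meta["forest"].to_numpy(),
        )
        table = ans.simulate_counts(meta, truth, cfg)
        cells = table.groupby(["site", "species", "period"])["count"].sum()
        var = 5.0 + 25.0 / 2.0  # NB variance
        se = np.sqrt(var / len(cells))
        assert abs(cells.mean() - 5.0) < 3 * se

    def test_mismatched_sites_raise(self, small_cfg):
        meta = ans.generate_landscape(small_cfg)
        _, truth = ans.generate_species_pool(small_cfg, meta)
        bad = meta.copy()
        bad["site"] = [f"Z{i}" for i in range(len(bad))]
        with pytest.raises(KeyError):
            ans.simulate_counts(bad, truth, small_cfg)

    def test_long_format_schema(self, small_dataset, small_cfg):
        table = small_dataset[3]
        assert list(table.columns) == ["site", "station", "species", "period", "count"]
        expected = (
            small_cfg.n_sites * small_cfg.n_stations
            * small_cfg.n_species * small_cfg.n_periods
        )
        assert len(table) == expected
        assert (table["count"] >= 0).all()


def test_dataset_roundtrip(tmp_path, small_cfg, small_dataset):
    meta, status, truth, table = small_dataset
    ans.write_dataset(tmp_path, small_cfg, meta, status, truth, table)
    back = ans.read_activity(tmp_path / "activity.csv")
    pd.testing.assert_frame_equal(back, table)
    assert (tmp_path / "config.txt").exists()
    assert (tmp_path / "ground_truth.csv").exists()
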