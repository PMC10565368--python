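import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import antseasons as ans

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cfg() -> ans.SimulationConfig:
    """A compact but structurally complete scenario: 6 sites, 2 stations,
    2 years of biweekly sampling, 12 species."""
    return ans.SimulationConfig(
        n_sites=6, n_stations=2, n_periods=52, n_species=12, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """(meta, status_table, truth, activity_table) for the small scenario."""
    return ans.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size default scenario (24 sites x 3 stations x 52 x 40)."""
    return ans.simulate_dataset(ans.SimulationConfig(seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_table() -> pd.DataFrame:
    """Hand-written 2-site, 2-station, 2-species, 3-period activity table."""
    rows = []
    for site in ("A", "B"):
        for station in ("s1", "s2"):
            for sp in ("x", "y"):
                for period in (1, 2, 3):
                    rows.append(
                        {
                            "site": site,
                            "station": station,
                            "species": sp,
                            "period": period,
                            "count": (period if sp == "x" else 2 * period)
                            + (10 if station == "s2" else 0),
                        }
                    )
    return pd.DataFrame(rows)
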