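import numpy as np
import pytest

import steppesim as ss
from steppesim.demography import ScenarioConfig, run_forward
from steppesim.geography import DemeIndex


@pytest.fixture(scope="session")
def europe():
    return ss.europe_grid()


@pytest.fixture(scope="session")
def observed(europe):
    return ss.load_observed(grid=europe)


@pytest.fixture(scope="session")
def toy_record():
    """Small two-layer run with full flow bookkeeping for oracle tests."""
    grid = ss.make_toy_world(10, 10, water_fraction=0.15, seed=3)
    scenario = ScenarioConfig(
        K_F=2000, K_P=2000, gamma_admix=0.02, ldd_rate=0.02,
        farmer_source=DemeIndex(0, 0),
        pastoralist_source=DemeIndex(grid.n_cols - 1, grid.n_rows - 1),
        pastoralist_onset_gen=20, n_generations=60, seed=11,
    )
    record = run_forward(scenario, grid, rng=np.random.default_rng(11),
                         record_flows_from=0)
    return record
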