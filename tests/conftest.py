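import numpy as np
import pytest

from replitrack import get_scenario, simulate_population
from replitrack.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def wt_params():
    return get_scenario("WT")


@pytest.fixture(scope="session")
def small_wt_population(wt_params):
    """25 rendered WT cells shared by detection/timeline/event tests."""
    return simulate_population(wt_params, 25, rng_seed=11)


@pytest.fixture(scope="session")
def small_wt_run():
    """A small end-to-end WT pipeline run with records kept in memory."""
    cfg = RunConfig(scenario="WT", n_cells=25, rng_seed=11)
    return run_pipeline(cfg)
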