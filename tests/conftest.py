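import numpy as np
import pandas as pd
import pytest

import beanpav as bp


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    cfg = bp.SimulationConfig(seed=11)
    return cfg, bp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def called_cohort(default_cohort):
    """Default cohort with simulated coverage and MIN-threshold calls."""
    cfg, cohort = default_cohort
    coverage, busco = bp.simulate_coverage(cohort, cfg)
    thresholds = bp.compute_thresholds(busco)
    pav = bp.call_presence(coverage, thresholds)
    return cfg, cohort, pav


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_matrix(rng):
    """Random 200 × 50 binary PAV matrix."""
    data = rng.integers(0, 2, size=(200, 50))
    return pd.DataFrame(
        data,
        index=[f"g{i}" for i in range(200)],
        columns=[f"a{j}" for j in range(50)],
    )
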