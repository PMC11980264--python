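import numpy as np
import pandas as pd
import pytest

import thermolag as tl
from thermolag.pipeline import RunConfig, run_main


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hump_truth():
    return tl.postnatal_heat_hump_truth()


@pytest.fixture(scope="session")
def small_cohort():
    """n=500 cohort with the postnatal heat surface, plus daily series."""
    truth = tl.postnatal_heat_hump_truth()
    cohort, daily = tl.simulate_cohort(500, truth, seed=7)
    return truth, cohort, daily


@pytest.fixture(scope="session")
def fitted_main(small_cohort):
    """Full pipeline result on the small cohort (no missingness)."""
    truth, cohort, daily = small_cohort
    res = run_main(RunConfig(seed=7, impute=False), cohort=cohort, daily=daily)
    return truth, res


@pytest.fixture(scope="session")
def toy_history():
    """Tiny deterministic exposure history: 4 subjects x 30 prenatal weeks."""
    rng = np.random.default_rng(3)
    mat = 12 + 6 * np.sin(np.linspace(0, 3, 30))[None, :] + rng.normal(0, 2, (4, 30))
    return tl.ExposureHistory(
        np.array(["a", "b", "c", "d"]), mat, "tmean", "prenatal"
    )
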