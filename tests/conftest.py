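import pandas as pd
import pytest

import plateletmir as pm
from plateletmir import reference

#: Canonical seed for every derandomized stochastic test in the suite.
TEST_SEED = 0


@pytest.fixture(scope="session")
def top10():
    """Reference per-day abundances of the ten dominant miRNAs."""
    return reference.top10_reads()


@pytest.fixture(scope="session")
def calibration():
    """(decay params, RQ calibration) preset mirroring the reference study."""
    return pm.reference_calibration()


@pytest.fixture(scope="session")
def rq_cohort(calibration):
    """A 100-bag validation cohort reduced to per-bag RQ values.

    Returns (rq results frame, cohort summary frame); generated once per
    session at the canonical seed.
    """
    _, rq_cal = calibration
    config = pm.SimulationConfig(n_bags=100, seed=TEST_SEED)
    ct = pm.simulate_ct(config, rq_cal)
    rq = pm.compute_rq(ct)
    return rq, pm.cohort_summary(rq)


@pytest.fixture()
def small_counts():
    """A tiny hand-written count matrix (3 miRNAs x 2 samples)."""
    return pd.DataFrame(
        {"s1": [3, 1, 0], "s2": [10, 10, 20]},
        index=pd.Index(["mir-a", "mir-b", "mir-c"], name="mirna_id"),
    )
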