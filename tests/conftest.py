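import numpy as np
import pytest

from cryptdrift.config import RunConfig
from cryptdrift.mtdna import DeficiencyThreshold, MutationRateSchedule
from cryptdrift.niche import FateParams, NicheConfig, simulate_ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def default_ensemble():
    """A shared multiscale ensemble at the default (study) parameters:
    3,000 crypts followed over 80 years, snapshotted every other year."""
    cfg = NicheConfig()
    summ = simulate_ensemble(
        cfg,
        FateParams(0.99),
        MutationRateSchedule(),
        DeficiencyThreshold(),
        n_runs=3000,
        record_ages=list(np.arange(20.0, 80.1, 2.0)),
        rng=11,
    )
    return summ
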