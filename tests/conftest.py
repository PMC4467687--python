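import numpy as np
import pytest

from decayfit import (
    BinSpec,
    BiexpParams,
    StudyConfig,
    bin_photons,
    run_study,
    simulate_photons,
)

# reduced-replication study reused by the acceptance tests: same grid and
# photon budget as the full design, 100 replicates per configuration
STUDY_REPS = 100
STUDY_SEED = 7


@pytest.fixture(scope="session")
def binspec():
    return BinSpec(delta=50.0, m=200)


@pytest.fixture(scope="session")
def truth():
    return BiexpParams(c=0.75, tau1=1500.0, tau2=750.0)


@pytest.fixture()
def small_hist(binspec, truth):
    times = simulate_photons(truth, 50, seed=42)
    return bin_photons(times, binspec)


@pytest.fixture(scope="session")
def study_result():
    cfg = StudyConfig(n_reps=STUDY_REPS, seed=STUDY_SEED, hellinger_n=2000)
    return run_study(cfg)
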