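import pytest

from ecdquant.synthetic_acquisition import (
    make_ground_truth,
    simulate_cohort,
    simulate_subject,
)


@pytest.fixture(scope="session")
def bundle():
    """One noiseless simulated subject at 35 ml/100g/min."""
    truth = make_ground_truth(35.0, seed=1)
    return simulate_subject(truth, noise="none", seed=1)


@pytest.fixture(scope="session")
def noisy_bundle():
    """One Poisson-noised subject."""
    truth = make_ground_truth(35.0, seed=3)
    return simulate_subject(truth, noise="poisson", seed=3)


@pytest.fixture(scope="session")
def cohort():
    """Noiseless 15-subject cohort spanning the clinical flow range."""
    return simulate_cohort(n_subjects=15, flow_range=(19.0, 45.0), seed=7)
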