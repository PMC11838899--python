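import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import mitofibre as mf

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_truth():
    """3 controls + 1 patient, 15% deficient, realistic defaults."""
    return mf.sample_ground_truth(seed=3, k=4, pi=0.15)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    data, labels = mf.generate_dataset(
        small_truth, n_per_subject=[200, 200, 200, 400], seed=4)
    return data, labels


@pytest.fixture(scope="session")
def fitted(small_dataset):
    """One reduced-preset Bayesian fit shared across read-only tests."""
    data, _ = small_dataset
    model = mf.HierarchicalMixtureModel(data)
    return model.fit(chains=2, iterations=3000, burn_in=1000, seed=5)


@pytest.fixture(scope="session")
def healthy_patient_fit():
    """Fit on a patient with zero deficient fibres (pi_true = 0)."""
    truth = mf.sample_ground_truth(seed=11, k=4, pi=0.0)
    data, labels = mf.generate_dataset(
        truth, n_per_subject=[150, 150, 150, 300], seed=12)
    assert labels.sum() == 0
    res = mf.HierarchicalMixtureModel(data).fit(
        chains=1, iterations=3000, burn_in=1000, seed=13)
    return truth, data, res
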