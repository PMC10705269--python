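import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import cmimpute as cm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    return cm.SyntheticSpec(n_species=8, n_tissues=4, n_probes=80, seed=1)


@pytest.fixture(scope="session")
def small_data(small_spec):
    """(individual dataset, full truth grid, held-out truth grid)."""
    return cm.generate(small_spec)


@pytest.fixture(scope="session")
def small_dataset(small_data):
    return small_data[0]


@pytest.fixture(scope="session")
def small_hyper():
    return cm.CVAEHyperparams(hidden_dims=(128, 64), epochs=150, seed=3)


@pytest.fixture(scope="session")
def small_model(small_dataset, small_hyper):
    """A CVAE trained well enough on the small fixture to reconstruct it."""
    return cm.train(small_dataset, small_dataset.label_space(), small_hyper)


@pytest.fixture()
def tiny_dataset():
    """Hand-written 4-sample, 3-probe dataset over 2 species x 2 tissues."""
    beta = np.array(
        [
            [0.2, 0.4, 0.9],
            [0.4, 0.6, 0.7],
            [0.7, 0.1, 0.5],
            [0.1, 0.9, 0.3],
        ]
    )
    return cm.MethylationDataset(
        beta,
        ["a1", "a2", "b1", "c1"],
        ["cat", "cat", "dog", "cat"],
        ["blood", "blood", "blood", "liver"],
        ["p1", "p2", "p3"],
    )
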