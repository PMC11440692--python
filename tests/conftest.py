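import numpy as np
import pytest

from mitomorph import (
    PerturbationConfig,
    SyntheticDatasetSpec,
    generate_ground_truth,
    reference_fixture,
)


@pytest.fixture(scope="session")
def small_gt():
    """Four synthetic images (one per grade), ~40-60 instances total."""
    return generate_ground_truth(SyntheticDatasetSpec(n_images=4, seed=11))


@pytest.fixture(scope="session")
def medium_gt():
    """Ten synthetic images, ~100 instances; shared by recovery tests."""
    return generate_ground_truth(SyntheticDatasetSpec(n_images=10, seed=5))


@pytest.fixture()
def fixture_pair():
    return reference_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
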