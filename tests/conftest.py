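import numpy as np
import pytest

from boneeis import GeneratorConfig, generate_dataset, make_grid


@pytest.fixture(scope="session")
def default_grid():
    return make_grid()


@pytest.fixture(scope="session")
def default_dataset():
    """The default 91-sample synthetic dataset at a fixed seed."""
    return generate_dataset(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def tiny_dataset():
    """Cheap 12-sample dataset (2 per class) on the default grid."""
    return generate_dataset(GeneratorConfig(seed=5, n_per_class=(2,) * 6))
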