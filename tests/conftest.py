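import numpy as np
import pytest

import mlpgrid as mg


@pytest.fixture(scope="session")
def milk_data():
    """Synthetic milk-shaped dataset at the study's sample size."""
    return mg.generate(mg.milk_defaults(seed=11))


@pytest.fixture(scope="session")
def tiny_design():
    """A 2x2x2 single-hidden-layer design (8 architectures)."""
    return mg.enumerate_design(
        mg.standard_group(1, nhl_levels=[3, 6], af_levels=[1, 3])
    )


@pytest.fixture(scope="session")
def fast_cfg():
    """Short training budget for sweep-level tests."""
    return mg.TrainConfig(seed=7, max_epochs=30)


@pytest.fixture(scope="session")
def linear_dataset():
    """Noiseless linear input-output data: y = A x + c."""
    rng = np.random.default_rng(42)
    X = rng.uniform(-1, 1, (80, 3))
    A = rng.uniform(-1, 1, (6, 3))
    c = rng.uniform(-0.5, 0.5, 6)
    return mg.Dataset(X, X @ A.T + c)
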