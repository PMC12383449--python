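import numpy as np
import pytest

from ivimid import DEFAULT_SCHEME, IVIMParameters


@pytest.fixture
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture
def gm_params():
    """Gray-matter-like IVIM ground truth."""
    return IVIMParameters(d=0.8e-3, d_star=0.02, f=0.15)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def exact_moment_sample(mean: float, sd: float, n: int, seed: int) -> np.ndarray:
    """A sample whose empirical mean and SD (ddof=1) equal the targets exactly."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * z
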