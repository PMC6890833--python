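import numpy as np
import pytest

from diagnet.eros import covariance_eigen
from diagnet.synthetic import SyntheticSpec, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """40 subjects, 10 regions, short series: fast but fully separable."""
    spec = SyntheticSpec(
        m=10,
        T=80,
        n_per_class=20,
        perturbed_pairs=[(0, 1), (2, 3), (4, 5), (6, 7)],
        delta=0.6,
        seed=7,
    )
    subjects, truth = make_dataset(spec)
    return spec, subjects, truth


def toy_eigen(diagonal):
    """EigenSummary of a diagonal covariance via a 2-region series oracle."""
    rng = np.random.default_rng(0)
    data = rng.standard_normal((50, len(diagonal))) * np.sqrt(diagonal)
    return covariance_eigen(data, n=len(diagonal))
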