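import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_correlation_pair(rng):
    """Two random well-conditioned correlation matrices of a given size."""

    def make(J: int):
        def one():
            A = rng.standard_normal((J, 3 * J))
            S = A @ A.T / (3 * J)
            d = np.sqrt(np.diag(S))
            return S / np.outer(d, d)

        return one(), one()

    return make
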