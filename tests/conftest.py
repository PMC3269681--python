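import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gpinet.datamodel import NodeDescriptor, SampleMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(values, kinds=None, space="raw", condition=None):
    """SampleMatrix from a plain array with autogenerated names/labels."""
    values = np.asarray(values, dtype=float)
    P, N = values.shape
    kinds = kinds or ["gene"] * P
    nodes = [NodeDescriptor(f"n{i + 1}", kinds[i]) for i in range(P)]
    return SampleMatrix(
        nodes=nodes,
        values=values,
        sample_ids=[f"s{k + 1}" for k in range(N)],
        condition=condition or ["c"] * N,
        space=space,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_raw_matrix():
    rng = np.random.default_rng(7)
    return make_matrix(np.exp(rng.normal(size=(3, 5))))
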