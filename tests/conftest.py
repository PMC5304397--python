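import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_tree():
    import dendropy

    return dendropy.Tree.get(
        data="((A:0.5,B:0.5):0.5,(C:0.3,D:0.3):0.7);",
        schema="newick",
        rooting="default-rooted",
    )
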