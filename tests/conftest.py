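import numpy as np
import pytest

from socialsurv.stream import StreamSpec, generate_stream, generate_users


@pytest.fixture(scope="session")
def small_spec():
    return StreamSpec(regions=["A", "B"], users_per_region=50, n_days=10,
                      base_rate=2.0, seed=11)


@pytest.fixture(scope="session")
def small_stream(small_spec):
    users, communities = generate_users(small_spec)
    messages, truth = generate_stream(small_spec, users)
    return users, communities, messages, truth


@pytest.fixture
def rng():
    # fresh generator per test so outcomes are order-independent
    return np.random.default_rng(2024)
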