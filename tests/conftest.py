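import pytest

from dhtpoly import SimParams, generate_tile_set, simulate_living


@pytest.fixture(scope="session")
def tile_system():
    return generate_tile_set(seed=1)


@pytest.fixture(scope="session")
def pop_ratio1():
    return simulate_living(SimParams(ratio_MI=1, n_initiators=10_000, seed=101))


@pytest.fixture(scope="session")
def pop_ratio10():
    return simulate_living(SimParams(ratio_MI=10, n_initiators=10_000, seed=110))
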