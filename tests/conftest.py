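import pytest

from ppicomplex import compute_close_bottlenecks, toy_network


@pytest.fixture(scope="session")
def toy():
    """(network, bottlenecks, expected complexes) of the worked-example graph."""
    return toy_network()


@pytest.fixture(scope="session")
def toy_index(toy):
    net, bots, _ = toy
    return compute_close_bottlenecks(net, bots)
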