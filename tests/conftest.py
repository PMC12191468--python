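import pytest

from ioqw import graph_io


@pytest.fixture(scope="session")
def karate():
    return graph_io.load_fixture("karate")


@pytest.fixture(scope="session")
def triangle():
    return graph_io.load_fixture("triangle")


@pytest.fixture(scope="session")
def path3():
    return graph_io.load_fixture("path3")


@pytest.fixture(scope="session")
def cycle6():
    return graph_io.load_fixture("cycle(6)")


def random_graph(rng, n_max=30, p=0.3, ensure_edge=True):
    """Small ER graph as a Graph, used by several property tests."""
    import numpy as np

    n = int(rng.integers(3, n_max + 1))
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                pairs.append((str(i), str(j)))
    if ensure_edge and not pairs:
        pairs = [("0", "1")]
    return graph_io.Graph.from_label_pairs(
        pairs, isolated=[str(i) for i in range(n)]
    )
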