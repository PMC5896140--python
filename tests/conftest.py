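import numpy as np
import pandas as pd
import pytest

from spermnet import BAGeneratorConfig, DirectedNetwork, EdgeRecord, generate_ba


def net_from_pairs(pairs, label="pp"):
    return DirectedNetwork(EdgeRecord(s, label, t) for s, t in pairs)


@pytest.fixture
def chain():
    """A -> B -> C."""
    return net_from_pairs([("A", "B"), ("B", "C")])


@pytest.fixture
def triangle():
    """Symmetric triangle: 6 directed edges among A, B, C."""
    pairs = [(a, b) for a in "ABC" for b in "ABC" if a != b]
    return net_from_pairs(pairs)


@pytest.fixture
def star():
    """Hub H with 4 leaves, edges both directions, no leaf-leaf edges."""
    pairs = []
    for leaf in ["L1", "L2", "L3", "L4"]:
        pairs += [("H", leaf), (leaf, "H")]
    return net_from_pairs(pairs)


@pytest.fixture(scope="session")
def ba_small():
    return generate_ba(BAGeneratorConfig(n_nodes=300, m=2, seed=1))


@pytest.fixture(scope="session")
def ba_small_metrics(ba_small):
    from spermnet import node_metrics

    return node_metrics(ba_small)


def to_pairs(net):
    return {(s, t) for (s, t, _l) in net.edge_keys()}
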