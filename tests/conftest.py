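from __future__ import annotations

import pytest

from netoverlap.data_io import GeneList, InteractionNetwork
from netoverlap.synthetic import SyntheticSpec, generate_network, plant_lists


@pytest.fixture
def chain_network() -> InteractionNetwork:
    """A-B, B-C path plus isolated gene D."""
    net = InteractionNetwork(edges=[("A", "B"), ("B", "C")])
    net.add_gene("D")
    return net


@pytest.fixture
def oracle_network() -> InteractionNetwork:
    """12-gene network small enough for exhaustive enumeration.

    A is a small hub; E..L form a path.  Universe/reference choices live in
    the tests that use it.
    """
    edges = [
        ("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"),
        ("D", "E"), ("E", "F"), ("F", "G"), ("G", "H"),
        ("H", "I"), ("I", "J"), ("J", "K"), ("K", "L"),
    ]
    return InteractionNetwork(edges=edges)


@pytest.fixture
def make_study():
    """Factory for a synthetic study: (network, gwas, hits, truth, universe)."""

    def _make(**kwargs):
        spec = SyntheticSpec(**kwargs)
        network = generate_network(spec)
        gwas, hits, truth, universe = plant_lists(network, spec)
        return network, gwas, hits, truth, universe, spec

    return _make


@pytest.fixture
def gene_list():
    def _make(name, genes):
        return GeneList.from_iterable(name, genes)

    return _make
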