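import numpy as np
import pytest
from scipy import sparse

from ribonet import NetworkParams, build_network
from ribonet.network import ContactRecord, NodeInfo, ResidueNetwork
from ribonet.structure_io import Category, ResidueClass
from ribonet.synthetic import (
    FixtureSpec,
    make_polymer,
    make_random_geometric,
    make_star,
    make_two_domain,
)


def toy_network(lengths: np.ndarray, classes=None, categories=None) -> ResidueNetwork:
    """ResidueNetwork from a dense edge-length matrix (for centrality tests
    that do not need a structure behind the graph)."""
    n = lengths.shape[0]
    classes = classes or [ResidueClass.AMINO_ACID] * n
    categories = categories or [None] * n
    nodes = [
        NodeInfo(chain_id="A", seq_number=i + 1, insertion_code="",
                 res_name="ALA", res_class=classes[i], category=categories[i],
                 n_atoms=1)
        for i in range(n)
    ]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if lengths[i, j] > 0:
                edges.append(ContactRecord(i, j, 1, 1.0 / lengths[i, j], lengths[i, j]))
    adj = sparse.csr_matrix(np.where(lengths > 0, lengths, 0.0))
    return ResidueNetwork(
        nodes=nodes, edges=edges, adjacency=adj, params=NetworkParams(),
        chain_positions=np.arange(n),
    )


def path_lengths(n: int, w: float = 1.0) -> np.ndarray:
    m = np.zeros((n, n))
    for i in range(n - 1):
        m[i, i + 1] = m[i + 1, i] = w
    return m


def star_lengths(n_leaves: int, w: float = 1.0) -> np.ndarray:
    m = np.zeros((n_leaves + 1, n_leaves + 1))
    m[0, 1:] = m[1:, 0] = w
    return m


@pytest.fixture(scope="session")
def polymer10():
    structure, edges = make_polymer(FixtureSpec(n_residues=10))
    return structure, edges, build_network(structure)


@pytest.fixture(scope="session")
def star7():
    structure, edges = make_star(FixtureSpec(n_residues=7))
    return structure, edges, build_network(structure)


@pytest.fixture(scope="session")
def two_domain21():
    structure, truth = make_two_domain(FixtureSpec(n_residues=21))
    return structure, truth, build_network(structure)


@pytest.fixture(scope="session")
def rgg30():
    structure, truth = make_random_geometric(
        FixtureSpec(n_residues=30, seed=1), target_mean_degree=6.0
    )
    return structure, truth, build_network(structure)
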