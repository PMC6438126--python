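"""Contact counting and assembly of the weighted residue network.

Two residues are linked when any of their heavy atoms lie within a cutoff
(default 4.5 Å, the conventional range for van der Waals and electrostatic
contacts).  The raw atom–atom contact count N_ij is normalised by the
residues' atom counts to give the local interaction strength

    a_ij = N_ij / (N_i · N_j)        (``product``, default)
    a_ij = N_ij / sqrt(N_i · N_j)    (``sqrt_product``)

which removes the size bias between small amino acids and large
nucleotides.  Edge length is 1/a_ij, so strongly interacting residues are
"close" and shortest paths track dense contact routes.  Covalently bonded
neighbours enter through their atom contacts exactly like nonbonded pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.stats import skew

from .structure_io import Category, ComponentAnnotation, Residue, ResidueClass, Structure

__all__ = [
    "NetworkParams",
    "ContactRecord",
    "NodeInfo",
    "ResidueNetwork",
    "count_contacts",
    "count_contacts_bruteforce",
    "interaction_strength",
    "build_network",
    "network_summary",
    "export_edges_tsv",
    "export_graphml",
]

NORMALIZATIONS = ("product", "sqrt_product")


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of network construction.

    cutoff: contact distance in Å (closed interval: d <= cutoff counts).
    normalization: denominator of the interaction strength.
    min_contacts: minimum N_ij for an edge to exist.
    """

    cutoff: float = 4.5
    normalization: str = "product"
    min_contacts: int = 1

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
        if self.min_contacts < 1:
            raise ValueError("min_contacts must be >= 1")


@dataclass(frozen=True)
class ContactRecord:
    i: int
    j: int
    n_contacts: int
    strength: float
    length: float

    def __post_init__(self):
        if not self.i < self.j:
            raise ValueError("contact stored with i < j")
        if self.n_contacts < 1 or self.strength <= 0 or self.length <= 0:
            raise ValueError("invalid contact record")


@dataclass(frozen=True)
class NodeInfo:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    res_class: ResidueClass
    category: Category | None
    n_atoms: int

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.res_name}{self.seq_number}{self.insertion_code}"


@dataclass
class ResidueNetwork:
    """Weighted undirected residue graph.

    ``adjacency`` stores edge lengths (1/a_ij) as a symmetric sparse matrix
    with a zero diagonal; ``edges`` stores each undirected edge once with
    i < j.  ``chain_positions`` gives each node's ordinal position within
    its chain so sequence-adjacent (bonded) edges can be told apart from
    long-range ones.
    """

    nodes: list[NodeInfo]
    edges: list[ContactRecord]
    adjacency: sparse.csr_matrix
    params: NetworkParams
    chain_positions: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        return np.diff(self.adjacency.indptr)

    def node_index(self) -> dict[tuple[str, int, str], int]:
        return {n.key: i for i, n in enumerate(self.nodes)}

    def is_bonded_edge(self, e: ContactRecord) -> bool:
        """Sequence-adjacent within the same chain (covalent neighbours)."""
        ni, nj = self.nodes[e.i], self.nodes[e.j]
        if ni.chain_id != nj.chain_id:
            return False
        return abs(int(self.chain_positions[e.i]) - int(self.chain_positions[e.j])) == 1


# ---------------------------------------------------------------------------
# contacts


def _atom_table(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    coords = np.concatenate([[a.coord for a in r.atoms] for r in structure.residues])
    owner = np.concatenate(
        [np.full(r.n_atoms, idx, dtype=np.int64) for idx, r in enumerate(structure.residues)]
    )
    return np.asarray(coords, float), owner


def count_contacts(structure: Structure, cutoff: float = 4.5) -> sparse.csr_matrix:
    """Inter-residue atom–atom contact counts N_ij within ``cutoff`` (closed).

    Uses a k-d tree over all heavy atoms; identical by contract to the
    all-pairs double loop (:func:`count_contacts_bruteforce`).
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords, owner = _atom_table(structure)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    n = len(structure)
    if pairs.size == 0:
        return sparse.csr_matrix((n, n), dtype=np.int64)
    ri = owner[pairs[:, 0]]
    rj = owner[pairs[:, 1]]
    mask = ri != rj
    ri, rj = ri[mask], rj[mask]
    lo, hi = np.minimum(ri, rj), np.maximum(ri, rj)
    mat = sparse.coo_matrix(
        (np.ones(lo.size, dtype=np.int64), (lo, hi)), shape=(n, n)
    ).tocsr()
    mat.sum_duplicates()
    return mat + mat.T


def count_contacts_bruteforce(structure: Structure, cutoff: float = 4.5) -> sparse.csr_matrix:
    """Reference all-pairs contact count (O(n_atoms²)); small inputs only."""
    coords, owner = _atom_table(structure)
    n = len(structure)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    within = d2 <= cutoff * cutoff
    mat = np.zeros((n, n), dtype=np.int64)
    ai, aj = np.nonzero(np.triu(within, k=1))
    for a, b in zip(ai, aj):
        i, j = owner[a], owner[b]
        if i != j:
            mat[i, j] += 1
            mat[j, i] += 1
    return sparse.csr_matrix(mat)


def interaction_strength(
    n_contacts: int, n_i: int, n_j: int, normalization: str = "product"
) -> float:
    """Local interaction strength a_ij from the contact count and atom counts."""
    if n_i < 1 or n_j < 1:
        raise ValueError("atom counts must be >= 1")
    if n_contacts < 1:
        raise ValueError("n_contacts must be >= 1")
    if normalization == "product":
        return n_contacts / (n_i * n_j)
    if normalization == "sqrt_product":
        return n_contacts / math.sqrt(n_i * n_j)
    raise ValueError(f"normalization must be one of {NORMALIZATIONS}")


# ---------------------------------------------------------------------------
# network assembly


def _chain_positions(residues: Sequence[Residue]) -> np.ndarray:
    pos = np.empty(len(residues), dtype=np.int64)
    counters: dict[str, int] = {}
    for idx, r in enumerate(residues):
        c = counters.get(r.chain_id, 0)
        pos[idx] = c
        counters[r.chain_id] = c + 1
    return pos


def build_network(
    structure: Structure,
    annotation: ComponentAnnotation | None = None,
    params: NetworkParams | None = None,
) -> ResidueNetwork:
    """Assemble the weighted residue network of a structure.

    One node per residue; an edge for every residue pair with at least
    ``params.min_contacts`` atom contacts, of length 1/a_ij.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    params = params or NetworkParams()
    contacts = count_contacts(structure, params.cutoff)

    nodes = [
        NodeInfo(
            chain_id=r.chain_id,
            seq_number=r.seq_number,
            insertion_code=r.insertion_code,
            res_name=r.res_name,
            res_class=r.res_class,
            category=annotation.category_of(r.chain_id) if annotation else None,
            n_atoms=r.n_atoms,
        )
        for r in structure.residues
    ]
    n_atoms = np.array([r.n_atoms for r in structure.residues], dtype=np.int64)

    upper = sparse.triu(contacts, k=1).tocoo()
    edges: list[ContactRecord] = []
    rows, cols, lens = [], [], []
    order = np.lexsort((upper.col, upper.row))
    for i, j, nij in zip(upper.row[order], upper.col[order], upper.data[order]):
        if nij < params.min_contacts:
            continue
        a = interaction_strength(int(nij), int(n_atoms[i]), int(n_atoms[j]), params.normalization)
        length = 1.0 / a
        edges.append(ContactRecord(int(i), int(j), int(nij), a, length))
        rows.append(i)
        cols.append(j)
        lens.append(length)
    n = len(nodes)
    adj = sparse.coo_matrix((lens, (rows, cols)), shape=(n, n))
    adj = (adj + adj.T).tocsr()
    return ResidueNetwork(
        nodes=nodes,
        edges=edges,
        adjacency=adj,
        params=params,
        chain_positions=_chain_positions(structure.residues),
    )


# ---------------------------------------------------------------------------
# summary & export


def network_summary(network: ResidueNetwork, n_bins: int = 50) -> dict:
    """Node/edge counts, degree statistics, and strength/length histograms
    split into bonded (sequence-adjacent) vs nonbonded edge classes."""
    if network.n_nodes == 0:
        raise ValueError("empty network")
    deg = network.degrees()
    out: dict = {
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "degree_mean": float(deg.mean()),
        "degree_sd": float(deg.std(ddof=0)),
        "normalization": network.params.normalization,
        "cutoff": network.params.cutoff,
    }
    bonded = np.array([network.is_bonded_edge(e) for e in network.edges], dtype=bool)
    strengths = np.array([e.strength for e in network.edges])
    lengths = np.array([e.length for e in network.edges])
    for label, mask in (("bonded", bonded), ("nonbonded", ~bonded)):
        s, ln = strengths[mask], lengths[mask]
        block: dict = {"n_edges": int(mask.sum())}
        if s.size:
            block["strength_hist"] = tuple(np.histogram(s, bins=n_bins))
            block["length_hist"] = tuple(np.histogram(ln, bins=n_bins))
            block["strength_mean"] = float(s.mean())
            # skew undefined for <3 points or an all-equal distribution
            if s.size > 2 and np.ptp(s) > 0:
                block["strength_skew"] = float(skew(s))
            else:
                block["strength_skew"] = float("nan")
        else:
            block["empty"] = True
        out[label] = block
    return out


def export_edges_tsv(network: ResidueNetwork, path, header_lines: Sequence[str] = ()) -> None:
    """Edge list as TSV: node labels, N_ij, a_ij, length."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("node_i\tnode_j\tn_contacts\tstrength\tlength\n")
        for e in network.edges:
            fh.write(
                f"{network.nodes[e.i].label}\t{network.nodes[e.j].label}\t"
                f"{e.n_contacts}\t{e.strength:.12g}\t{e.length:.12g}\n"
            )


def export_graphml(network: ResidueNetwork, path) -> None:
    """GraphML export for external viewers (via networkx)."""
    import networkx as nx

    g = nx.Graph()
    for idx, node in enumerate(network.nodes):
        g.add_node(
            idx,
            label=node.label,
            res_class=node.res_class.value,
            category=node.category.value if node.category else "",
            n_atoms=node.n_atoms,
        )
    for e in network.edges:
        g.add_edge(e.i, e.j, n_contacts=e.n_contacts, strength=e.strength, weight=e.length)
    nx.write_graphml(g, path)
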