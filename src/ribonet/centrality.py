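"""Degree, weighted closeness and weighted betweenness centrality.

Shortest paths run over edge lengths 1/a_ij.  Closeness of node l is

    CC(l) = N / Σ_j d_lj

with N the number of nodes in the graph, so it carries units of inverse
edge length.  Betweenness is the pair-normalised fraction of shortest
paths passing through a node,

    CB(l) = [ Σ_{i<j, i≠l≠j} σ_ij(l) / σ_ij ] / [ (N−1)(N−2)/2 ],

which lies in [0, 1].  σ counting over real-valued lengths uses a relative
tie tolerance so that equally short routes are recognised reproducibly.
The implementation is a tie-tolerant Dijkstra census with Brandes-style
dependency accumulation; its contract is equality with exhaustive path
enumeration on small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from heapq import heappop, heappush

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .network import ResidueNetwork

__all__ = [
    "DisconnectedError",
    "ShortestPathCensus",
    "CentralityTable",
    "TIE_TOL",
    "degree_centrality",
    "shortest_path_census",
    "closeness_centrality",
    "betweenness_centrality",
    "centrality_table",
]

#: relative tolerance for recognising equal-length shortest paths
TIE_TOL = 1e-9


class DisconnectedError(ValueError):
    """Raised when a connected graph is required but components exist."""

    def __init__(self, labels: np.ndarray):
        self.n_components = int(labels.max()) + 1
        sizes = np.bincount(labels)
        super().__init__(
            f"network has {self.n_components} connected components "
            f"(sizes {sorted(sizes.tolist(), reverse=True)}); "
            "pass per_component=True to analyse components separately"
        )
        self.labels = labels


@dataclass
class ShortestPathCensus:
    """Distances and shortest-path counts from one source node."""

    source: int
    dist: np.ndarray  # d_lj; inf for unreachable
    sigma: np.ndarray  # number of minimum-length paths (within tie tolerance)

    @property
    def reachable(self) -> np.ndarray:
        return np.isfinite(self.dist)


@dataclass
class CentralityTable:
    """Per-node centralities with graph metadata."""

    frame: pd.DataFrame
    n_nodes: int
    connected: bool
    tie_tol: float

    @property
    def degree(self) -> np.ndarray:
        return self.frame["degree"].to_numpy()

    @property
    def closeness(self) -> np.ndarray:
        return self.frame["closeness"].to_numpy()

    @property
    def betweenness(self) -> np.ndarray:
        return self.frame["betweenness"].to_numpy()


def _graph_arrays(adjacency: sparse.csr_matrix):
    adj = adjacency.tocsr()
    return adj.indptr, adj.indices, adj.data


def degree_centrality(network: ResidueNetwork) -> np.ndarray:
    """Number of edges incident to each node (unweighted count)."""
    return network.degrees().astype(np.int64)


def _sssp(indptr, indices, weights, source: int, n: int, tie_tol: float):
    """Tie-tolerant Dijkstra from ``source``.

    Returns (dist, sigma, predecessor lists, settle order).  A predecessor v
    of w is any settled node with d(v) + w(v,w) within relative ``tie_tol``
    of d(w); sigma accumulates over all predecessors.
    """
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    preds: list[list[int]] = [[] for _ in range(n)]
    done = np.zeros(n, dtype=bool)
    dist[source] = 0.0
    sigma[source] = 1.0
    heap: list[tuple[float, int]] = [(0.0, source)]
    order: list[int] = []
    while heap:
        d, v = heappop(heap)
        if done[v]:
            continue
        done[v] = True
        order.append(v)
        for k in range(indptr[v], indptr[v + 1]):
            w = indices[k]
            if done[w]:
                continue
            nd = d + weights[k]
            tol = tie_tol * max(nd, dist[w]) if np.isfinite(dist[w]) else 0.0
            if nd < dist[w] - tol:
                dist[w] = nd
                sigma[w] = sigma[v]
                preds[w] = [v]
                heappush(heap, (nd, w))
            elif abs(nd - dist[w]) <= tol:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return dist, sigma, preds, order


def shortest_path_census(
    network: ResidueNetwork, source: int, tie_tol: float = TIE_TOL
) -> ShortestPathCensus:
    """Dijkstra distances and shortest-path counts from ``source``."""
    n = network.n_nodes
    if not 0 <= source < n:
        raise IndexError(f"source {source} out of range")
    indptr, indices, weights = _graph_arrays(network.adjacency)
    dist, sigma, _, _ = _sssp(indptr, indices, weights, source, n, tie_tol)
    return ShortestPathCensus(source=source, dist=dist, sigma=sigma)


def _components(network: ResidueNetwork) -> np.ndarray:
    n_comp, labels = connected_components(network.adjacency, directed=False)
    return labels


def closeness_centrality(
    network: ResidueNetwork,
    per_component: bool = False,
    numerator: str = "N",
    tie_tol: float = TIE_TOL,
) -> np.ndarray:
    """Weighted closeness CC(l) = N / Σ_j d_lj.

    ``numerator="N"`` uses the node count of the graph (or, per component,
    the component size); ``"N-1"`` uses the conventional excess count.
    Disconnected graphs raise unless ``per_component`` is set.
    """
    if numerator not in ("N", "N-1"):
        raise ValueError("numerator must be 'N' or 'N-1'")
    n = network.n_nodes
    if n == 1:
        return np.zeros(1)
    labels = _components(network)
    if labels.max() > 0 and not per_component:
        raise DisconnectedError(labels)
    indptr, indices, weights = _graph_arrays(network.adjacency)
    out = np.zeros(n)
    for comp in range(labels.max() + 1):
        members = np.flatnonzero(labels == comp)
        size = members.size
        if size == 1:
            out[members[0]] = 0.0
            continue
        num = size if numerator == "N" else size - 1
        for v in members:
            dist, _, _, _ = _sssp(indptr, indices, weights, int(v), n, tie_tol)
            out[v] = num / dist[members].sum()
    return out


def betweenness_centrality(
    network: ResidueNetwork,
    per_component: bool = False,
    tie_tol: float = TIE_TOL,
) -> np.ndarray:
    """Pair-normalised weighted betweenness in [0, 1], endpoints excluded.

    Brandes accumulation over the tie-tolerant shortest-path census; for a
    disconnected graph (with ``per_component``) each component is normalised
    by its own pair count.
    """
    n = network.n_nodes
    labels = _components(network)
    if labels.max() > 0 and not per_component:
        raise DisconnectedError(labels)
    indptr, indices, weights = _graph_arrays(network.adjacency)
    acc = np.zeros(n)
    for s in range(n):
        dist, sigma, preds, order = _sssp(indptr, indices, weights, s, n, tie_tol)
        delta = np.zeros(n)
        for w in reversed(order):
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in preds[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                acc[w] += delta[w]
    # each unordered pair counted from both endpoints
    out = np.zeros(n)
    for comp in range(labels.max() + 1):
        members = np.flatnonzero(labels == comp)
        size = members.size
        if size > 2:
            out[members] = acc[members] / ((size - 1) * (size - 2))
    return out


def centrality_table(
    network: ResidueNetwork,
    per_component: bool = False,
    numerator: str = "N",
    tie_tol: float = TIE_TOL,
) -> CentralityTable:
    """All three centralities plus betweenness quantile ranks, one row per node.

    Deterministic given the network and the tie tolerance.
    """
    deg = degree_centrality(network)
    cc = closeness_centrality(network, per_component=per_component,
                              numerator=numerator, tie_tol=tie_tol)
    cb = betweenness_centrality(network, per_component=per_component, tie_tol=tie_tol)
    # fraction of nodes with score <= own score (max rank for ties)
    order = np.argsort(cb, kind="stable")
    ranks = np.empty(network.n_nodes)
    sorted_cb = cb[order]
    counts = np.searchsorted(sorted_cb, cb, side="right")
    ranks = counts / network.n_nodes
    frame = pd.DataFrame(
        {
            "chain": [nd.chain_id for nd in network.nodes],
            "resnum": [nd.seq_number for nd in network.nodes],
            "icode": [nd.insertion_code for nd in network.nodes],
            "resname": [nd.res_name for nd in network.nodes],
            "class": [nd.res_class.value for nd in network.nodes],
            "component": [nd.category.value if nd.category else "" for nd in network.nodes],
            "degree": deg,
            "closeness": cc,
            "betweenness": cb,
            "betweenness_quantile_rank": ranks,
        }
    )
    labels = _components(network)
    return CentralityTable(
        frame=frame,
        n_nodes=network.n_nodes,
        connected=bool(labels.max() == 0),
        tie_tol=tie_tol,
    )
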