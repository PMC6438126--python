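"""Independent brute-force oracles used only by the tests.

Centralities are recomputed from scratch here: Floyd–Warshall distances
followed by explicit enumeration of every shortest path.  Nothing is
shared with the package's Dijkstra/Brandes implementation, so agreement
is a real cross-check.
"""

from __future__ import annotations

import numpy as np

REL_TOL = 1e-9


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest distances; ``lengths`` dense, 0 = no edge."""
    n = lengths.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    ii, jj = np.nonzero(lengths)
    dist[ii, jj] = lengths[ii, jj]
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return dist


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= REL_TOL * max(abs(a), abs(b), 1e-300)


def enumerate_shortest_paths(lengths: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Every minimum-length path s→t as an explicit node sequence."""
    dist = floyd_warshall(lengths)
    if not np.isfinite(dist[s, t]):
        return []
    paths: list[list[int]] = []

    def walk(node: int, acc: list[int]) -> None:
        if node == t:
            paths.append(acc.copy())
            return
        for v in range(lengths.shape[0]):
            w = lengths[node, v]
            if w > 0 and _close(w + dist[v, t], dist[node, t]):
                acc.append(v)
                walk(v, acc)
                acc.pop()

    walk(s, [s])
    return paths


def betweenness_by_enumeration(lengths: np.ndarray) -> np.ndarray:
    """Pair-normalised betweenness with endpoint exclusion, from explicit
    path enumeration over all unordered pairs."""
    n = lengths.shape[0]
    acc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_shortest_paths(lengths, s, t)
            if not paths:
                continue
            sigma = len(paths)
            for p in paths:
                for node in p[1:-1]:
                    acc[node] += 1.0 / sigma
    if n > 2:
        acc /= (n - 1) * (n - 2) / 2.0
    return acc


def closeness_by_enumeration(lengths: np.ndarray, numerator: str = "N") -> np.ndarray:
    dist = floyd_warshall(lengths)
    n = lengths.shape[0]
    num = n if numerator == "N" else n - 1
    return num / dist.sum(axis=1)


def sigma_by_enumeration(lengths: np.ndarray, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Distances and shortest-path counts from one source."""
    n = lengths.shape[0]
    dist = floyd_warshall(lengths)[s]
    sigma = np.zeros(n)
    for t in range(n):
        if t == s:
            sigma[t] = 1.0
        elif np.isfinite(dist[t]):
            sigma[t] = len(enumerate_shortest_paths(lengths, s, t))
    return dist, sigma


def network_lengths(network) -> np.ndarray:
    """Dense edge-length matrix of a ResidueNetwork."""
    return network.adjacency.toarray()
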