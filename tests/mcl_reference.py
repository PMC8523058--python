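"""Dense-matrix reference implementation of Markov clustering.

Written straight from the algorithm definition (expansion = matrix square,
inflation = entrywise power + column renormalization, prune, interpret the
limit's support as clusters) with plain dense numpy — independent of the
sparse implementation in the package.
"""

from __future__ import annotations

import numpy as np


def mcl_reference_clusters(
    n_nodes: int,
    edges: dict[tuple[int, int], float],
    inflation: float = 2.0,
    prune_threshold: float = 1e-8,
    tol: float = 1e-8,
    max_iterations: int = 1000,
) -> list[frozenset[int]]:
    """Cluster an undirected weighted graph over nodes 0..n_nodes-1.

    Self-loop weight per node = its maximum incident edge weight (1 for an
    isolated node, which comes back as a singleton).
    """
    A = np.zeros((n_nodes, n_nodes))
    for (i, j), w in edges.items():
        A[i, j] = A[j, i] = w
    loops = A.max(axis=0)
    connected = loops > 0
    np.fill_diagonal(A, np.where(connected, loops, 0.0))

    idx = np.flatnonzero(connected)
    clusters: list[frozenset[int]] = []
    if idx.size:
        M = A[np.ix_(idx, idx)].astype(float)
        M = M / M.sum(axis=0, keepdims=True)
        for _ in range(max_iterations):
            prev = M.copy()
            M = M @ M
            M = np.power(M, inflation)
            M[M < prune_threshold] = 0.0
            colsum = M.sum(axis=0, keepdims=True)
            colsum[colsum == 0] = 1.0
            M = M / colsum
            if np.abs(M - prev).max() < tol:
                break
        support = (M + M.T) > 0
        # connected components of the support, by naive BFS
        seen = set()
        for start in range(len(idx)):
            if start in seen:
                continue
            comp = {start}
            frontier = [start]
            while frontier:
                v = frontier.pop()
                for w in np.flatnonzero(support[v]):
                    if w not in comp:
                        comp.add(int(w))
                        frontier.append(int(w))
            seen |= comp
            clusters.append(frozenset(int(idx[v]) for v in comp))
    in_cluster = {v for c in clusters for v in c}
    for v in range(n_nodes):
        if v not in in_cluster:
            clusters.append(frozenset([v]))
    return clusters
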