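"""Graph Clustering Merger: combine disjoint subalignments into one MSA.

The merge treats every *column* of every subalignment as a node of a
weighted undirected graph.  Backbone alignments — small alignments spanning
all subsets — provide the evidence: whenever a backbone column places
residues from two subalignment columns together, the edge between those
columns gains support.  The graph is clustered with Markov clustering
(MCL), clusters are repaired so that no cluster holds two columns of the
same subalignment, ordered into a *trace* consistent with every
subalignment's column order, and finally emitted as the merged alignment
(one output column per cluster).
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence as TypingSequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse import csgraph

from .msa import GAP, Alignment

logger = logging.getLogger(__name__)

#: A node of the alignment graph: (subalignment_index, column_index).
Node = tuple[int, int]

DEFAULT_INFLATION = 2.0
DEFAULT_PRUNE_THRESHOLD = 1e-8
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITERATIONS = 1000


# ---------------------------------------------------------------------------
# Alignment graph
# ---------------------------------------------------------------------------


@dataclass
class AlignmentGraph:
    """Weighted support graph over all subalignment columns.

    ``column_counts[i]`` is the column count of subalignment ``i`` (the node
    set is implicit: every (i, c) with c < column_counts[i]).  ``edges`` maps
    canonically ordered node pairs to positive integer support counts.
    """

    column_counts: list[int]
    edges: dict[tuple[Node, Node], int] = field(default_factory=dict)

    def n_nodes(self) -> int:
        return sum(self.column_counts)

    def nodes(self) -> Iterator[Node]:
        for si, count in enumerate(self.column_counts):
            for c in range(count):
                yield (si, c)

    def add_support(self, a: Node, b: Node, weight: int = 1) -> None:
        if a == b:
            return
        key = (a, b) if a <= b else (b, a)
        self.edges[key] = self.edges.get(key, 0) + weight

    def weight(self, a: Node, b: Node) -> int:
        key = (a, b) if a <= b else (b, a)
        return self.edges.get(key, 0)


def build_graph(
    subalignments: TypingSequence[Alignment],
    backbone_alignments: Iterable[Alignment],
) -> AlignmentGraph:
    """Compile backbone alignments into the alignment graph.

    Every backbone residue maps, via its ungapped site index, to the column
    of its home subalignment that holds the same residue.  For each backbone
    column, each unordered pair of *upper-case* residues adds one unit of
    support to the edge between their home columns (pairs landing on the
    same node add nothing).  Supplying a backbone twice doubles its
    contribution — support is additive over the backbone multiset.
    """
    home: dict[str, tuple[int, list[int]]] = {}
    for si, sub in enumerate(subalignments):
        for rid in sub.row_ids:
            if rid in home:
                raise ValueError(f"row {rid!r} appears in two subalignments")
            home[rid] = (si, sub.site_to_column(rid))
    return build_graph_from_maps(
        [sub.length for sub in subalignments], home, backbone_alignments
    )


def build_graph_from_maps(
    column_counts: TypingSequence[int],
    home: dict[str, tuple[int, list[int]]],
    backbone_alignments: Iterable[Alignment],
) -> AlignmentGraph:
    """Graph construction from per-row site→column maps.

    ``home[rid] = (subalignment_index, site_to_column)``.  This is the
    memory-light entry point: callers may extract the maps one subalignment
    at a time and never hold two subalignments together.
    """
    graph = AlignmentGraph(list(column_counts))
    for backbone in backbone_alignments:
        for rid in backbone.row_ids:
            if rid not in home:
                raise KeyError(f"backbone row {rid!r} not found in any subalignment")
        site_counters = {rid: -1 for rid in backbone.row_ids}
        for col in range(backbone.length):
            # Group this column's upper-case cells by home node; support
            # between two nodes is (cells in u) x (cells in v).
            cells: dict[Node, int] = {}
            for rid in backbone.row_ids:
                ch = backbone.row(rid)[col]
                if ch == GAP:
                    continue
                site_counters[rid] += 1
                if not ch.isupper():
                    continue
                si, cols = home[rid]
                node = (si, cols[site_counters[rid]])
                cells[node] = cells.get(node, 0) + 1
            if len(cells) < 2:
                continue
            for (u, nu), (v, nv) in itertools.combinations(cells.items(), 2):
                graph.add_support(u, v, nu * nv)
    return graph


def write_graph(graph: AlignmentGraph, path: str | Path) -> None:
    """Stable text dump: one ``si:col si:col weight`` line per edge."""
    with open(path, "w") as fh:
        fh.write(" ".join(str(c) for c in graph.column_counts) + "\n")
        for (a, b), w in sorted(graph.edges.items()):
            fh.write(f"{a[0]}:{a[1]} {b[0]}:{b[1]} {w}\n")


def read_graph(path: str | Path) -> AlignmentGraph:
    with open(path) as fh:
        counts = [int(x) for x in fh.readline().split()]
        graph = AlignmentGraph(counts)
        for line in fh:
            sa, sb, w = line.split()
            a = tuple(int(x) for x in sa.split(":"))
            b = tuple(int(x) for x in sb.split(":"))
            graph.edges[(a, b)] = int(w)
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


def mcl_cluster(
    graph: AlignmentGraph,
    inflation: float = DEFAULT_INFLATION,
    self_loop_weight: float | None = None,
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    tol: float = DEFAULT_TOL,
) -> list[set[Node]]:
    """Markov clustering of the alignment graph.

    Builds the column-stochastic transition matrix with self-loops (default
    self-loop weight: the node's maximum incident edge weight), then
    alternates expansion (matrix squaring) and inflation (entrywise power
    ``inflation``, renormalize), pruning entries below ``prune_threshold``,
    until the matrix changes by less than ``tol`` or ``max_iterations`` is
    hit (then the current state is interpreted, with a warning).  Clusters
    are the connected components of the converged matrix's support;
    isolated graph nodes come back as singletons.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    connected = sorted({n for pair in graph.edges for n in pair})
    clusters: list[set[Node]] = []
    if connected:
        idx = {n: i for i, n in enumerate(connected)}
        m = len(connected)
        rows, cols, vals = [], [], []
        max_incident = np.zeros(m)
        for (a, b), w in graph.edges.items():
            ia, ib = idx[a], idx[b]
            rows += [ia, ib]
            cols += [ib, ia]
            vals += [float(w), float(w)]
            max_incident[ia] = max(max_incident[ia], w)
            max_incident[ib] = max(max_incident[ib], w)
        loops = (
            np.full(m, self_loop_weight) if self_loop_weight is not None
            else max_incident
        )
        rows += list(range(m))
        cols += list(range(m))
        vals += list(loops)
        M = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
        M = _normalize_columns(M)
        converged = False
        for _ in range(max_iterations):
            prev = M.copy()
            M = M @ M
            M.data = np.power(M.data, inflation)
            M.data[M.data < prune_threshold] = 0.0
            M.eliminate_zeros()
            M = _normalize_columns(M)
            delta = abs(M - prev)
            if delta.nnz == 0 or delta.max() < tol:
                converged = True
                break
        if not converged:
            logger.warning(
                "MCL did not converge in %d iterations; interpreting the "
                "current matrix", max_iterations,
            )
        support = M + M.T
        n_comp, assignment = csgraph.connected_components(support, directed=False)
        comp_sets: list[set[Node]] = [set() for _ in range(n_comp)]
        for node, comp in zip(connected, assignment):
            comp_sets[comp].add(node)
        clusters.extend(cs for cs in comp_sets if cs)
    in_cluster = {n for cs in clusters for n in cs}
    for node in graph.nodes():
        if node not in in_cluster:
            clusters.append({node})
    clusters.sort(key=lambda cs: min(cs))
    return clusters


def _normalize_columns(M: sp.csr_matrix) -> sp.csr_matrix:
    colsum = np.asarray(M.sum(axis=0)).ravel()
    colsum[colsum == 0] = 1.0
    D = sp.diags(1.0 / colsum)
    return (M @ D).tocsr()


# ---------------------------------------------------------------------------
# Cluster validity and trace ordering
# ---------------------------------------------------------------------------


def enforce_cluster_validity(
    clusters: list[set[Node]], graph: AlignmentGraph
) -> list[set[Node]]:
    """Split clusters holding two columns of one subalignment.

    Per offending subalignment, the column with the greatest total edge
    weight into the cluster is kept (tie: lower column index); the rest are
    evicted into singleton clusters.
    """
    out: list[set[Node]] = []
    for cluster in clusters:
        by_sub: dict[int, list[Node]] = {}
        for node in cluster:
            by_sub.setdefault(node[0], []).append(node)
        if all(len(v) == 1 for v in by_sub.values()):
            out.append(set(cluster))
            continue
        keep: set[Node] = set()
        evicted: list[Node] = []
        for si, nodes in by_sub.items():
            if len(nodes) == 1:
                keep.add(nodes[0])
                continue
            scored = sorted(
                nodes,
                key=lambda n: (
                    -sum(graph.weight(n, m) for m in cluster if m != n),
                    n[1],
                ),
            )
            keep.add(scored[0])
            evicted.extend(scored[1:])
        out.append(keep)
        out.extend({n} for n in evicted)
    out.sort(key=lambda cs: min(cs))
    return out


@dataclass
class Trace:
    """Ordered clusters, ≤1 column per subalignment each — the merged columns."""

    clusters: list[dict[int, int]]  # per cluster: subalignment -> column

    def validate(self, column_counts: TypingSequence[int]) -> None:
        last_seen = {si: -1 for si in range(len(column_counts))}
        seen_counts = [0] * len(column_counts)
        for cluster in self.clusters:
            for si, col in cluster.items():
                if col <= last_seen[si]:
                    raise AssertionError(
                        f"trace violates column order of subalignment {si}: "
                        f"{col} after {last_seen[si]}"
                    )
                last_seen[si] = col
                seen_counts[si] += 1
        for si, count in enumerate(column_counts):
            if seen_counts[si] != count:
                raise AssertionError(
                    f"trace covers {seen_counts[si]}/{count} columns of "
                    f"subalignment {si}"
                )


def _build_precedence(
    clusters: list[set[Node]], column_counts: TypingSequence[int]
) -> tuple[nx.DiGraph, dict[Node, int]]:
    """Digraph over cluster ids; edge X→Y supported by subalignment s iff
    consecutive columns of s sit in X then Y.  Consecutive edges generate
    the full precedence relation by transitivity, so cycle detection and
    topological order on them are equivalent to the full relation."""
    cluster_of: dict[Node, int] = {}
    for ci, cs in enumerate(clusters):
        for node in cs:
            cluster_of[node] = ci
    dg = nx.DiGraph()
    dg.add_nodes_from(range(len(clusters)))
    for si, count in enumerate(column_counts):
        prev = None
        for c in range(count):
            ci = cluster_of[(si, c)]
            if prev is not None and prev != ci:
                if dg.has_edge(prev, ci):
                    dg[prev][ci]["support"].add(si)
                else:
                    dg.add_edge(prev, ci, support={si})
            elif prev == ci:
                raise AssertionError(
                    "invalid cluster: two columns of one subalignment"
                )
            prev = ci
    return dg, cluster_of


def order_clusters(
    clusters: list[set[Node]],
    graph: AlignmentGraph,
) -> Trace:
    """Order valid clusters into a trace, greedily breaking order conflicts.

    Precedence: cluster X precedes Y when some subalignment has a column in
    X before a column in Y.  While the precedence digraph has a cycle, one
    node is moved out of its cluster into a singleton: the candidate whose
    removal destroys the most cycle-supporting precedence edges per unit of
    support weight lost, with a deterministic tie-break on the smallest
    (subalignment, column).  The acyclic result is topologically sorted,
    ties resolved by the smallest member node.
    """
    working = [set(cs) for cs in clusters]
    column_counts = graph.column_counts
    while True:
        dg, _ = _build_precedence(working, column_counts)
        sccs = [scc for scc in nx.strongly_connected_components(dg) if len(scc) > 1]
        if not sccs:
            break
        scc = min(sccs, key=lambda s: min(s))
        scc_edges = [
            (u, v, dg[u][v]["support"])
            for u, v in dg.edges
            if u in scc and v in scc
        ]
        best = None  # (-score, node)
        for ci in sorted(scc):
            cluster = working[ci]
            if len(cluster) < 2:
                continue
            for node in sorted(cluster):
                s = node[0]
                destroyed = sum(
                    1
                    for u, v, supp in scc_edges
                    if supp == {s} and (u == ci or v == ci)
                )
                pairs_lost = sum(
                    graph.weight(node, m) for m in cluster if m != node
                )
                score = destroyed / (1.0 + pairs_lost)
                cand = (-score, node, ci)
                if best is None or cand < best:
                    best = cand
        if best is None:
            raise AssertionError("cyclic precedence with no splittable cluster")
        _, node, ci = best
        working[ci].discard(node)
        working.append({node})
        working = [cs for cs in working if cs]
    dg, _ = _build_precedence(working, column_counts)
    # Deterministic Kahn topological sort: smallest member node first.
    indeg = {ci: dg.in_degree(ci) for ci in dg.nodes}
    heap = [(min(working[ci]), ci) for ci in dg.nodes if indeg[ci] == 0]
    heapq.heapify(heap)
    order: list[int] = []
    while heap:
        _, ci = heapq.heappop(heap)
        order.append(ci)
        for succ in dg.successors(ci):
            indeg[succ] -= 1
            if indeg[succ] == 0:
                heapq.heappush(heap, (min(working[succ]), succ))
    if len(order) != len(list(dg.nodes)):
        raise AssertionError("precedence digraph still cyclic after repair")
    trace = Trace([{si: c for si, c in sorted(working[ci])} for ci in order])
    trace.validate(column_counts)
    return trace


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def iter_merged_rows(
    trace: Trace,
    get_subalignment: Callable[[int], Alignment],
    n_subalignments: int,
) -> Iterator[tuple[str, str]]:
    """Yield merged rows subalignment by subalignment.

    Only one subalignment needs to be resident at a time: the caller's
    ``get_subalignment`` may load lazily and evict after each iteration.
    """
    for si in range(n_subalignments):
        sub = get_subalignment(si)
        cols = [cluster.get(si) for cluster in trace.clusters]
        for rid, row in sub.rows():
            yield rid, "".join(GAP if c is None else row[c] for c in cols)


def assemble(trace: Trace, subalignments: TypingSequence[Alignment]) -> Alignment:
    """Materialize the merged alignment: one output column per trace cluster."""
    ids, rows = [], {}
    for rid, row in iter_merged_rows(
        trace, lambda si: subalignments[si], len(subalignments)
    ):
        ids.append(rid)
        rows[rid] = row
    return Alignment(ids, rows)


def merge_subalignments(
    subalignments: TypingSequence[Alignment],
    backbone_alignments: Iterable[Alignment],
    inflation: float = DEFAULT_INFLATION,
) -> Alignment:
    """Convenience one-shot merge: graph → MCL → validity → trace → assembly."""
    graph = build_graph(subalignments, backbone_alignments)
    clusters = mcl_cluster(graph, inflation=inflation)
    clusters = enforce_cluster_validity(clusters, graph)
    trace = order_clusters(clusters, graph)
    return assemble(trace, subalignments)


def disjoint_block_merge(subalignments: TypingSequence[Alignment]) -> Alignment:
    """Naive no-evidence merge: concatenate subalignments into disjoint
    column blocks (every cross-subset homology is lost).  Serves as the
    floor any informed merge must beat."""
    total = sum(sub.length for sub in subalignments)
    ids, rows = [], {}
    offset = 0
    for sub in subalignments:
        for rid, row in sub.rows():
            ids.append(rid)
            rows[rid] = GAP * offset + row + GAP * (total - offset - sub.length)
        offset += sub.length
    return Alignment(ids, rows)


def write_clusters(clusters: list[set[Node]], path: str | Path) -> None:
    """One line per cluster: space-separated ``si:col`` tokens."""
    with open(path, "w") as fh:
        for cs in clusters:
            fh.write(" ".join(f"{si}:{c}" for si, c in sorted(cs)) + "\n")
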