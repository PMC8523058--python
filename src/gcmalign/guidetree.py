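"""Guide trees and centroid edge decomposition.

The pipeline only needs a *rough* phylogeny to split the dataset into
subsets; accuracy of the final alignment comes from the merge step, not the
guide tree.  Three sources are supported:

* a user-supplied Newick file,
* the built-in fallback: k-mer-profile cosine distances + neighbor joining,
* random decomposition (no tree at all, maximum speed).

External tree estimators (FastTree, Clustal Omega initial tree, MAFFT
PartTree) can be plugged in as subprocess adapters that emit Newick; see
:class:`ExternalTreeAdapter`.

Decomposition deletes, recursively, the *centroid edge* — the edge whose
removal minimizes the leaf count of the larger side — until every piece has
at most ``max_subset_size`` leaves.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import dendropy
import numpy as np

from .msa import NUCLEOTIDE_LETTERS, Sequence


class GuideTree:
    """An unrooted leaf-labeled tree wrapping a dendropy ``Tree``."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def __len__(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    # Adjacency over nodes with stable integer ids; leaves carry labels.
    def adjacency(self) -> tuple[dict[int, list[int]], dict[int, str]]:
        ids: dict[int, int] = {}
        labels: dict[int, str] = {}
        adj: dict[int, list[int]] = {}
        for i, node in enumerate(self._tree.preorder_node_iter()):
            ids[id(node)] = i
            adj[i] = []
            if node.taxon is not None:
                labels[i] = node.taxon.label
        for node in self._tree.preorder_node_iter():
            for child in node.child_nodes():
                a, b = ids[id(node)], ids[id(child)]
                adj[a].append(b)
                adj[b].append(a)
        for i in adj:
            adj[i].sort()
        return adj, labels


def parse_newick(source: str | Path) -> GuideTree:
    """Parse a Newick tree from a path or a literal Newick string."""
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in guide tree")
    return GuideTree(tree)


def write_newick(tree: GuideTree, path: str | Path) -> None:
    tree.dendropy_tree.write(
        path=str(path), schema="newick", unquoted_underscores=True
    )


# ---------------------------------------------------------------------------
# Built-in fallback tree: k-mer cosine distances + NJ
# ---------------------------------------------------------------------------


def _kmer_profile(residues: str, k: int) -> dict[str, int]:
    prof: dict[str, int] = {}
    for i in range(max(0, len(residues) - k + 1)):
        kmer = residues[i : i + k]
        prof[kmer] = prof.get(kmer, 0) + 1
    return prof


def _cosine_distance(p: dict[str, int], q: dict[str, int]) -> float:
    if not p or not q:
        return 1.0
    dot = sum(v * q.get(kmer, 0) for kmer, v in p.items())
    np_ = math.sqrt(sum(v * v for v in p.values()))
    nq = math.sqrt(sum(v * v for v in q.values()))
    if np_ == 0 or nq == 0:
        return 1.0
    return max(0.0, 1.0 - dot / (np_ * nq))


def default_k(sequences: TypingSequence[Sequence]) -> int:
    """k=5 for nucleotide data, k=3 for amino acids (rough-tree heuristic)."""
    letters = {c for s in sequences[:50] for c in s.residues[:200].upper()}
    return 5 if letters <= NUCLEOTIDE_LETTERS else 3


def build_fallback_tree(
    sequences: TypingSequence[Sequence], k: int | None = None, seed: int = 0
) -> GuideTree:
    """Distance tree from k-mer count profiles.

    Pairwise distance is 1 − cosine similarity of k-mer count vectors; the
    tree is neighbor joining on that matrix (below four taxa the pair is
    joined directly).  Deterministic for a fixed input order and seed.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    if k is None:
        k = default_k(sequences)
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(sequences)
    labels = [s.id for s in sequences]
    if n == 1:
        tree = dendropy.Tree.get(
            data=f"({_quote(labels[0])});", schema="newick",
            preserve_underscores=True,
        )
        return GuideTree(tree)
    profiles = [_kmer_profile(s.residues.upper(), k) for s in sequences]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _cosine_distance(profiles[i], profiles[j])
            # tiny index-keyed offset makes every pairwise distance unique,
            # so agglomeration picks are unambiguous and the tree is
            # reproducible across processes even for tied profiles
            d += 1e-9 * (i * n + j)
            dist[i, j] = dist[j, i] = d
    tree = _nj_tree(labels, dist)
    return GuideTree(tree)


def _quote(label: str) -> str:
    return label.replace(" ", "_")


def _nj_tree(labels: list[str], dist: np.ndarray) -> dendropy.Tree:
    """Deterministic neighbor joining (ties: lowest active-node indices).

    With fewer than four taxa agglomeration order is immaterial, so the
    taxa are joined by nearest pair (UPGMA-style) directly.
    """
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)

    def leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = ns.new_taxon(label)
        return node

    nodes: dict[int, dendropy.Node] = {i: leaf(lab)
                                       for i, lab in enumerate(labels)}
    D = {(i, j): float(dist[i, j])
         for i in range(len(labels)) for j in range(i + 1, len(labels))}

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else D[(min(i, j), max(i, j))]

    active = sorted(nodes)
    next_id = len(labels)
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active) for i in active}
        best = min(
            ((m - 2) * d(i, j) - r[i] - r[j], i, j)
            for ii, i in enumerate(active)
            for j in active[ii + 1 :]
        )
        _, i, j = best
        bl_i = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        bl_j = d(i, j) - bl_i
        parent = dendropy.Node()
        nodes[i].edge.length = max(bl_i, 0.0)
        nodes[j].edge.length = max(bl_j, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        for k in active:
            if k not in (i, j):
                D[(min(k, next_id), max(k, next_id))] = 0.5 * (
                    d(i, k) + d(j, k) - d(i, j)
                )
        nodes[next_id] = parent
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    root = tree.seed_node
    if len(active) == 3:
        i, j, k = active
        for a, bl in ((i, 0.5 * (d(i, j) + d(i, k) - d(j, k))),
                      (j, 0.5 * (d(i, j) + d(j, k) - d(i, k))),
                      (k, 0.5 * (d(i, k) + d(j, k) - d(i, j)))):
            nodes[a].edge.length = max(bl, 0.0)
            root.add_child(nodes[a])
    elif len(active) == 2:
        i, j = active
        for a in (i, j):
            nodes[a].edge.length = d(i, j) / 2.0
            root.add_child(nodes[a])
    else:
        root.add_child(nodes[active[0]])
    return tree


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------


@dataclass
class DecompositionResult:
    """Disjoint, covering id subsets, each within the configured maximum."""

    subsets: list[list[str]]

    def validate(self, all_ids: Iterable[str], max_subset_size: int) -> None:
        flat = [i for s in self.subsets for i in s]
        if len(flat) != len(set(flat)):
            raise AssertionError("decomposition subsets overlap")
        if set(flat) != set(all_ids):
            raise AssertionError("decomposition does not cover the dataset")
        if any(len(s) == 0 for s in self.subsets):
            raise AssertionError("empty subset in decomposition")
        if any(len(s) > max_subset_size for s in self.subsets):
            raise AssertionError("subset exceeds maximum size")


def random_decomposition(
    ids: TypingSequence[str], max_subset_size: int, seed: int = 0
) -> DecompositionResult:
    """Shuffle and chunk ids into ⌈n/max⌉ near-equal subsets."""
    if max_subset_size < 1:
        raise ValueError("max_subset_size must be >= 1")
    ids = list(ids)
    rng = random.Random(seed)
    rng.shuffle(ids)
    n = len(ids)
    n_chunks = max(1, math.ceil(n / max_subset_size))
    base, rem = divmod(n, n_chunks)
    subsets, start = [], 0
    for i in range(n_chunks):
        size = base + (1 if i < rem else 0)
        subsets.append(ids[start : start + size])
        start += size
    return DecompositionResult(subsets)


def centroid_edge_decompose(
    tree: GuideTree, max_subset_size: int
) -> DecompositionResult:
    """Recursively delete centroid edges until all pieces are small enough.

    The centroid edge of a piece is the edge whose removal minimizes the
    leaf count of the larger side; ties go to the edge met first in a
    deterministic traversal rooted at the lexicographically first leaf.
    """
    if max_subset_size < 1:
        raise ValueError("max_subset_size must be >= 1")
    adj, labels = tree.adjacency()
    all_leaves = sorted(labels.values())
    if not all_leaves:
        raise ValueError("guide tree has no leaves")

    subsets: list[list[str]] = []

    def split(nodes: set[int]) -> None:
        piece_leaves = [labels[v] for v in nodes if v in labels]
        if len(piece_leaves) <= max_subset_size:
            subsets.append(sorted(piece_leaves))
            return
        root = min(v for v in nodes if v in labels and labels[v] == min(piece_leaves))
        # Iterative post-order DFS computing subtree leaf counts; the edge
        # (parent, v) splits into count(v) vs total - count(v).
        total = len(piece_leaves)
        parent: dict[int, int] = {root: -1}
        order: list[int] = []
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            for w in adj[v]:
                if w in nodes and w not in parent:
                    parent[w] = v
                    stack.append(w)
        count = {v: (1 if v in labels else 0) for v in parent}
        for v in reversed(order):
            if parent[v] != -1:
                count[parent[v]] += count[v]
        best_edge, best_larger = None, total + 1
        for v in reversed(order):  # post-order: children before parents
            p = parent[v]
            if p == -1:
                continue
            larger = max(count[v], total - count[v])
            if larger < best_larger:
                best_larger, best_edge = larger, (p, v)
        assert best_edge is not None
        p, v = best_edge
        # Component containing v after deleting (p, v).
        side: set[int] = {v}
        stack = [v]
        while stack:
            x = stack.pop()
            for w in adj[x]:
                if w in nodes and w not in side and not (x == v and w == p):
                    side.add(w)
                    stack.append(w)
        other = nodes - side
        if not (side & set(labels)) or not (other & set(labels)):
            raise AssertionError("centroid split produced an empty side")
        split(side)
        split(other)

    split(set(adj))
    subsets.sort(key=lambda s: s[0])
    result = DecompositionResult(subsets)
    result.validate(all_leaves, max_subset_size)
    return result


# ---------------------------------------------------------------------------
# External tree adapters (optional subprocess hooks)
# ---------------------------------------------------------------------------


@dataclass
class ExternalTreeAdapter:
    """Subprocess contract for an external guide-tree estimator.

    ``command_template`` is formatted with ``{input}`` (unaligned FASTA path)
    and ``{output}`` (Newick path the tool must write).  Any tool honoring
    the contract can serve: FastTree (with or without maximum likelihood),
    Clustal Omega's initial tree, MAFFT's PartTree, ...
    """

    name: str
    command_template: str

    def estimate(self, fasta_path: str | Path, newick_out: str | Path) -> GuideTree:
        import shlex
        import subprocess

        cmd = self.command_template.format(
            input=str(fasta_path), output=str(newick_out)
        )
        proc = subprocess.run(
            shlex.split(cmd), capture_output=True, text=True
        )
        if proc.returncode != 0 or not Path(newick_out).is_file():
            raise RuntimeError(
                f"external tree tool {self.name!r} failed: {proc.stderr[-500:]}"
            )
        return parse_newick(Path(newick_out))
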