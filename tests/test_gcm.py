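"""Alignment graph construction, MCL, cluster validity, trace, assembly."""

import random

import pytest

from gcmalign.gcm import (
    AlignmentGraph,
    Trace,
    assemble,
    build_graph,
    disjoint_block_merge,
    enforce_cluster_validity,
    mcl_cluster,
    merge_subalignments,
    order_clusters,
)
from gcmalign.msa import Alignment, homologous_pairs, restrict
from gcmalign.metrics import compare_alignments
from gcmalign.simulate import SimConfig, simulate
from mcl_reference import mcl_reference_clusters


def two_subalignments():
    return [
        Alignment(["a"], {"a": "AC"}),
        Alignment(["b"], {"b": "AC"}),
    ]


class TestBuildGraph:
    def test_no_backbones_no_edges(self):
        g = build_graph(two_subalignments(), [])
        assert g.edges == {} and g.n_nodes() == 4

    def test_single_column_support(self):
        subs = two_subalignments()
        backbone = Alignment(["a", "b"], {"a": "AC", "b": "AC"})
        g = build_graph(subs, [backbone])
        assert g.edges == {
            ((0, 0), (1, 0)): 1,
            ((0, 1), (1, 1)): 1,
        }

    def test_additivity_under_duplication(self):
        subs = two_subalignments()
        backbone = Alignment(["a", "b"], {"a": "AC", "b": "AC"})
        g1 = build_graph(subs, [backbone])
        g2 = build_graph(subs, [backbone, backbone])
        assert g2.edges == {k: 2 * w for k, w in g1.edges.items()}

    def test_lowercase_backbone_letters_ignored(self):
        subs = two_subalignments()
        backbone = Alignment(["a", "b"], {"a": "aC", "b": "AC"})
        g = build_graph(subs, [backbone])
        assert g.edges == {((0, 1), (1, 1)): 1}

    def test_unknown_backbone_row_rejected(self):
        backbone = Alignment(["zz"], {"zz": "AC"})
        with pytest.raises(KeyError):
            build_graph(two_subalignments(), [backbone])


class TestMCL:
    def graph_from_edges(self, n, edges):
        g = AlignmentGraph([n])
        for (i, j), w in edges.items():
            g.add_support((0, i), (0, j), w)
        return g

    def test_two_triangles(self):
        edges = {(0, 1): 1, (1, 2): 1, (0, 2): 1,
                 (3, 4): 1, (4, 5): 1, (3, 5): 1}
        clusters = mcl_cluster(self.graph_from_edges(6, edges))
        sets = sorted(sorted(c[1] for c in cs) for cs in clusters)
        assert sets == [[0, 1, 2], [3, 4, 5]]

    def test_isolated_node_singleton(self):
        clusters = mcl_cluster(self.graph_from_edges(1, {}))
        assert clusters == [{(0, 0)}]

    def test_complete_graph_one_cluster(self):
        edges = {(i, j): 1 for i in range(4) for j in range(i + 1, 4)}
        clusters = mcl_cluster(self.graph_from_edges(4, edges))
        assert len(clusters) == 1 and len(clusters[0]) == 4

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl_cluster(self.graph_from_edges(2, {(0, 1): 1}), inflation=1.0)

    def test_matches_dense_reference_on_random_graphs(self):
        rng = random.Random(123)
        for rep in range(50):
            n = rng.randint(2, 30)
            edges = {}
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.2:
                        edges[(i, j)] = rng.randint(1, 5)
            ours = mcl_cluster(self.graph_from_edges(n, edges))
            ours_sets = sorted(sorted(c[1] for c in cs) for cs in ours)
            ref = mcl_reference_clusters(n, {k: float(v)
                                             for k, v in edges.items()})
            ref_sets = sorted(sorted(cs) for cs in ref)
            assert ours_sets == ref_sets, f"rep {rep}, n={n}"


class TestClusterValidity:
    def test_valid_clusters_unchanged(self):
        g = AlignmentGraph([2, 1])
        clusters = [{(0, 0), (1, 0)}, {(0, 1)}]
        assert enforce_cluster_validity(clusters, g) == [
            {(0, 0), (1, 0)}, {(0, 1)},
        ]

    def test_heavier_column_kept(self):
        g = AlignmentGraph([2, 1])
        g.add_support((0, 0), (1, 0), 3)
        g.add_support((0, 1), (1, 0), 1)
        out = enforce_cluster_validity([{(0, 0), (0, 1), (1, 0)}], g)
        assert sorted(out, key=min) == [{(0, 0), (1, 0)}, {(0, 1)}]

    def test_tie_keeps_lower_column(self):
        g = AlignmentGraph([2, 1])
        g.add_support((0, 0), (1, 0), 2)
        g.add_support((0, 1), (1, 0), 2)
        out = enforce_cluster_validity([{(0, 0), (0, 1), (1, 0)}], g)
        assert {(0, 0), (1, 0)} in out and {(0, 1)} in out


class TestOrdering:
    def test_consistent_chain(self):
        g = AlignmentGraph([2, 2])
        clusters = [{(0, 0), (1, 0)}, {(0, 1), (1, 1)}]
        trace = order_clusters(clusters, g)
        assert trace.clusters == [{0: 0, 1: 0}, {0: 1, 1: 1}]

    def test_two_cycle_resolved_into_three_clusters(self):
        g = AlignmentGraph([2, 2])
        clusters = [{(0, 0), (1, 1)}, {(0, 1), (1, 0)}]
        trace = order_clusters(clusters, g)
        assert len(trace.clusters) == 3
        trace.validate([2, 2])

    def test_all_singletons_valid(self):
        g = AlignmentGraph([3, 2])
        clusters = [{(si, c)} for si in range(2)
                    for c in range(g.column_counts[si])]
        trace = order_clusters(clusters, g)
        trace.validate([3, 2])


class TestAssembly:
    def test_single_subalignment_identity(self):
        sub = Alignment(["a", "b"], {"a": "A-C", "b": "AGC"})
        g = AlignmentGraph([3])
        trace = order_clusters([{(0, c)} for c in range(3)], g)
        assert assemble(trace, [sub]) == sub

    def test_two_blocks_stacked_column_by_column(self):
        subs = [
            Alignment(["a"], {"a": "AC"}),
            Alignment(["b"], {"b": "GT"}),
        ]
        trace = Trace([{0: 0, 1: 0}, {0: 1, 1: 1}])
        merged = assemble(trace, subs)
        assert merged.row("a") == "AC" and merged.row("b") == "GT"
        assert merged.length == 2

    def test_disjoint_block_merge_loses_cross_pairs(self):
        subs = [
            Alignment(["a"], {"a": "AC"}),
            Alignment(["b"], {"b": "AC"}),
        ]
        merged = disjoint_block_merge(subs)
        assert merged.length == 4
        assert merged.row("a") == "AC--" and merged.row("b") == "--AC"
        assert homologous_pairs(merged) == set()


class TestConsistentBackboneOracle:
    def test_induced_restrictions_merge_exactly(self):
        """Subalignments and backbones induced from one reference alignment
        must merge back to it: the reference's pairs are recovered and the
        SP error is zero."""
        true_aln, _, _ = simulate(
            SimConfig(n_taxa=16, seed=2, substitution_rate=0.2)
        )
        ids = true_aln.row_ids
        subsets = [ids[i::3] for i in range(3)]
        subs = [restrict(true_aln, s) for s in subsets]
        subset_of = {rid: si for si, s in enumerate(subsets) for rid in s}
        rng = random.Random(0)
        backbones = [
            restrict(true_aln,
                     [rid for s in subsets for rid in rng.sample(s, 2)])
            for _ in range(6)
        ]
        for col in range(true_aln.length):
            members = [rid for rid in ids if true_aln.row(rid)[col] != "-"]
            if len({subset_of[r] for r in members}) >= 2:
                backbones.append(restrict(true_aln, members))
        merged = merge_subalignments(subs, backbones)
        res = compare_alignments(merged, true_aln)
        assert res.sp_error == 0.0
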