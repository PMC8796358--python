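"""Divide-and-conquer aligner: distances, trees, DP, graph merge, MCL."""

import math

import numpy as np
import pytest

from fragalign.dc_aligner import (
    AlignmentGraph,
    MergeConfig,
    Scoring,
    align_backbone,
    align_unaligned,
    build_alignment_graph,
    build_support_alignments,
    centroid_decompose,
    kmer_distance_matrix,
    mcl,
    nj_tree,
    pairwise_align,
    progressive_align,
    resolve_and_merge,
)
from fragalign.msa_core import Alignment, Sequence, parse_newick

from conftest import exhaustive_affine_score, random_sequences


class TestKmerDistances:
    def test_identical_sequences_distance_zero(self):
        seqs = [Sequence("a", "ACGTACGT"), Sequence("b", "ACGTACGT")]
        d = kmer_distance_matrix(seqs, 4)
        assert d[0, 1] == pytest.approx(0.0)

    def test_disjoint_kmers_distance_one(self):
        seqs = [Sequence("a", "AAAAAA"), Sequence("b", "CCCCCC")]
        d = kmer_distance_matrix(seqs, 4)
        assert d[0, 1] == pytest.approx(1.0)

    def test_hand_computed_cosine(self):
        # ACGTACGT 4-mers: ACGT x2, CGTA, GTAC, TACG; ACGTACGA: each once + ACGA
        seqs = [Sequence("a", "ACGTACGT"), Sequence("b", "ACGTACGA")]
        d = kmer_distance_matrix(seqs, 4)
        expected = 1.0 - 5.0 / (math.sqrt(7) * math.sqrt(5))
        assert d[0, 1] == pytest.approx(expected)

    def test_symmetric_zero_diagonal(self, rng):
        seqs = random_sequences(rng, 5, 10, 20)
        d = kmer_distance_matrix(seqs, 3)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


class TestNJTree:
    def test_additive_four_taxon_split_recovered(self):
        dist = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 2],
                [6, 6, 2, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(dist, ["a", "b", "c", "d"])
        clades = {
            frozenset(t.name for t in node.tips())
            for node in tree.non_tips(include_self=True)
        }
        assert frozenset({"a", "b"}) in clades or frozenset({"c", "d"}) in clades

    def test_three_taxa(self):
        tree = nj_tree(np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]), list("abc"))
        assert sorted(t.name for t in tree.tips()) == ["a", "b", "c"]

    def test_two_taxa_single_edge(self):
        tree = nj_tree(np.array([[0.0, 1.5], [1.5, 0.0]]), ["a", "b"])
        tips = {t.name: t.length for t in tree.tips()}
        assert sum(tips.values()) == pytest.approx(1.5)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1], [2, 0.0]]), ["a", "b"])


class TestCentroidDecompose:
    def test_small_tree_single_subset(self):
        tree = parse_newick("((a,b),(c,d));")
        decomp = centroid_decompose(tree, 10)
        assert decomp.subsets == [frozenset("abcd")]

    def test_balanced_four_leaf_splits_at_internal_edge(self):
        tree = parse_newick("((a,b),(c,d));")
        decomp = centroid_decompose(tree, 2)
        assert sorted(decomp.subsets, key=min) == [
            frozenset({"a", "b"}),
            frozenset({"c", "d"}),
        ]

    def test_caterpillar_contiguous_subsets(self):
        tree = parse_newick("(((((a,b),c),d),e),f);")
        decomp = centroid_decompose(tree, 2)
        union = set().union(*decomp.subsets)
        assert union == set("abcdef")
        assert all(len(s) <= 2 for s in decomp.subsets)
        # the first split is the balanced 3|3 spine edge
        assert frozenset({"a", "b"}) in decomp.subsets
        assert frozenset({"d", "e"}) in decomp.subsets

    def test_partition_property(self, rng):
        seqs = random_sequences(rng, 17, 20, 30)
        tree = nj_tree(kmer_distance_matrix(seqs, 4), [s.id for s in seqs])
        decomp = centroid_decompose(tree, 5)
        union = set().union(*decomp.subsets)
        assert union == {s.id for s in seqs}
        assert all(1 <= len(s) <= 5 for s in decomp.subsets)


class TestPairwiseAffineDP:
    def test_simple_pair(self):
        score, aln = pairwise_align(Sequence("x", "ACGT"), Sequence("y", "AGT"))
        assert score == pytest.approx(exhaustive_affine_score("ACGT", "AGT"))
        assert aln.ungapped("x") == "ACGT" and aln.ungapped("y") == "AGT"

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed):
        r = np.random.default_rng(seed)
        x = "".join("ACGT"[c] for c in r.integers(0, 4, int(r.integers(1, 7))))
        y = "".join("ACGT"[c] for c in r.integers(0, 4, int(r.integers(1, 7))))
        score, _ = pairwise_align(Sequence("x", x), Sequence("y", y))
        assert score == pytest.approx(exhaustive_affine_score(x, y), abs=1e-9)

    def test_length_eight_pair(self):
        x, y = "ACGTACGT", "AGTACG"
        score, _ = pairwise_align(Sequence("x", x), Sequence("y", y))
        assert score == pytest.approx(exhaustive_affine_score(x, y), abs=1e-9)

    def test_custom_scoring_respected(self):
        sc = Scoring(match=1.0, mismatch=-2.0, gap_open=-3.0, gap_extend=-1.0)
        score, _ = pairwise_align(Sequence("x", "AAAA"), Sequence("y", "AA"), sc)
        assert score == pytest.approx(
            exhaustive_affine_score("AAAA", "AA", 1.0, -2.0, -3.0, -1.0)
        )


class TestProgressiveAlign:
    def test_identical_sequences_no_gaps(self):
        seqs = [Sequence(f"s{i}", "ACGTACGT") for i in range(4)]
        tree = parse_newick("((s0,s1),(s2,s3));")
        aln = progressive_align(seqs, tree)
        assert aln.n_columns == 8
        assert all("-" not in row for row in aln.rows.values())

    def test_single_sequence_alignment(self):
        aln = align_unaligned([Sequence("a", "ACGT")])
        assert aln.rows == {"a": "ACGT"}

    def test_residue_conservation(self, rng):
        seqs = random_sequences(rng, 7, 10, 30)
        aln = align_unaligned(seqs)
        for s in seqs:
            assert aln.ungapped(s.id) == s.residues

    def test_guide_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError):
            progressive_align([Sequence("a", "AC")], parse_newick("(a,b);"))


class TestSupportAlignments:
    def _subsets(self):
        return [
            Alignment({"a": "ACGT", "b": "ACGT"}),
            Alignment({"c": "ACGT", "d": "ACGT"}),
        ]

    def test_count_and_coverage(self):
        cfg = MergeConfig(support_count=3, support_sample_size=1, seed=0)
        supports = build_support_alignments(self._subsets(), cfg)
        assert len(supports) == 3
        for sup in supports:
            ids = set(sup.rows)
            assert ids & {"a", "b"} and ids & {"c", "d"}

    def test_two_singleton_subsets_pairwise(self):
        subsets = [Alignment({"a": "ACGT"}), Alignment({"b": "AGT"})]
        supports = build_support_alignments(subsets, MergeConfig(seed=1))
        for sup in supports:
            assert set(sup.rows) == {"a", "b"}


class TestAlignmentGraph:
    def test_no_supports_no_edges(self):
        graph = build_alignment_graph(
            [Alignment({"a": "AC"}), Alignment({"b": "AC"})], []
        )
        assert graph.edges == {}
        assert len(graph.nodes) == 4

    def test_residue_pair_weights(self):
        # two 3-row subsets, one support aligning all 6 rows without gaps:
        # each support column holds 3+3 residues -> 9 cross pairs per column
        sub0 = Alignment({f"a{i}": "AC" for i in range(3)})
        sub1 = Alignment({f"b{i}": "AC" for i in range(3)})
        support = Alignment({**sub0.rows, **sub1.rows})
        graph = build_alignment_graph([sub0, sub1], [support])
        assert graph.weight((0, 0), (1, 0)) == 9
        assert graph.weight((0, 1), (1, 1)) == 9
        assert graph.weight((0, 0), (1, 1)) == 0

    def test_within_subset_edges_forbidden(self):
        g = AlignmentGraph([(0, 0), (0, 1)])
        with pytest.raises(ValueError):
            AlignmentGraph([(0, 0), (0, 1)], {frozenset({(0, 0), (0, 1)}): 1})
        assert g.edges == {}


class TestMCL:
    def test_disconnected_edges_stay_separate(self):
        g = AlignmentGraph([(0, 0), (0, 1), (1, 0), (1, 1)])
        g.add_edge((0, 0), (1, 0), 5)
        g.add_edge((0, 1), (1, 1), 5)
        clusters = mcl(g, MergeConfig())
        assert sorted(sorted(c) for c in clusters) == [
            [(0, 0), (1, 0)],
            [(0, 1), (1, 1)],
        ]

    def test_triangle_plus_isolated_node(self):
        g = AlignmentGraph([(0, 0), (1, 0), (2, 0), (0, 1)])
        g.add_edge((0, 0), (1, 0), 2)
        g.add_edge((1, 0), (2, 0), 2)
        g.add_edge((0, 0), (2, 0), 2)
        clusters = mcl(g, MergeConfig())
        as_sets = sorted(clusters, key=len)
        assert as_sets[0] == {(0, 1)}
        assert as_sets[1] == {(0, 0), (1, 0), (2, 0)}

    def test_every_node_clustered_exactly_once(self, rng):
        nodes = [(s, c) for s in range(3) for c in range(4)]
        g = AlignmentGraph(nodes)
        for _ in range(10):
            u, v = rng.choice(len(nodes), 2, replace=False)
            if nodes[u][0] != nodes[v][0]:
                g.add_edge(nodes[u], nodes[v], int(rng.integers(1, 5)))
        clusters = mcl(g, MergeConfig())
        flat = [n for c in clusters for n in c]
        assert sorted(flat) == sorted(nodes)


class TestResolveAndMerge:
    def test_compatible_clusters_merge_gapless(self):
        subs = [Alignment({"a": "ACG"}), Alignment({"b": "ATG"})]
        clusters = [{(0, i), (1, i)} for i in range(3)]
        merged = resolve_and_merge(clusters, subs)
        assert merged.n_columns == 3
        assert merged.rows == {"a": "ACG", "b": "ATG"}

    def test_illegal_cluster_split_before_ordering(self):
        subs = [Alignment({"a": "AC"}), Alignment({"b": "A"})]
        g = AlignmentGraph([(0, 0), (0, 1), (1, 0)])
        g.add_edge((0, 0), (1, 0), 5)
        g.add_edge((0, 1), (1, 0), 1)
        clusters = [{(0, 0), (0, 1), (1, 0)}]
        merged = resolve_and_merge(clusters, subs, g)
        # heavier column (0,0) stays fused with (1,0); (0,1) is evicted
        assert merged.rows["a"].replace("-", "") == "AC"
        assert merged.rows["b"].replace("-", "") == "A"
        a_row, b_row = merged.rows["a"], merged.rows["b"]
        fused = a_row.index("A")
        assert b_row[fused] == "A"

    def test_crossing_clusters_cycle_broken_by_weight(self):
        subs = [Alignment({"a": "AC"}), Alignment({"b": "GT"})]
        g = AlignmentGraph([(0, 0), (0, 1), (1, 0), (1, 1)])
        g.add_edge((0, 0), (1, 1), 5)
        g.add_edge((0, 1), (1, 0), 1)
        clusters = [{(0, 0), (1, 1)}, {(0, 1), (1, 0)}]
        merged = resolve_and_merge(clusters, subs, g)
        # both subsets keep their column order
        assert merged.ungapped("a") == "AC"
        assert merged.ungapped("b") == "GT"
        # the heavy pairing (a column 0, b column 1) survives in one column
        col_a0 = merged.rows["a"].index("A")
        assert merged.rows["b"][col_a0] == "T"

    def test_incomplete_cover_rejected(self):
        subs = [Alignment({"a": "AC"})]
        with pytest.raises(ValueError):
            resolve_and_merge([{(0, 0)}], subs)


class TestAlignBackbone:
    def test_small_input_equals_progressive(self, rng):
        seqs = random_sequences(rng, 6, 15, 25)
        direct = align_backbone(seqs, max_subset_size=50)
        assert direct.rows == align_unaligned(seqs).rows

    def test_near_identical_two_subsets_gapless(self):
        seqs = [Sequence(f"s{i}", "ACGTACGTACGTACGT") for i in range(8)]
        aln = align_backbone(seqs, max_subset_size=4)
        assert aln.n_columns == 16
        assert all("-" not in row for row in aln.rows.values())

    def test_deterministic(self, rng):
        seqs = random_sequences(rng, 10, 20, 40)
        cfg = MergeConfig(seed=3)
        a = align_backbone(seqs, max_subset_size=4, merge_config=cfg)
        b = align_backbone(seqs, max_subset_size=4, merge_config=cfg)
        assert a.rows == b.rows

    def test_conservation_through_merge(self, rng):
        seqs = random_sequences(rng, 12, 25, 45)
        aln = align_backbone(seqs, max_subset_size=5, merge_config=MergeConfig(seed=1))
        for s in seqs:
            assert aln.ungapped(s.id) == s.residues
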