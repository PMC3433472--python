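import itertools

import numpy as np
import pytest

from selexkit.distfam import (
    DistanceGraph, build_dendrogram, build_distance_graph, call_families,
    call_sequence_families, call_structure_families, components_at_threshold,
    edit_distance, letter_label, roman_numeral, structure_distance,
    structure_to_tree, tree_edit_distance,
)
from selexkit.errors import InputError
from selexkit.rnastructure import StructureRecord

from conftest import make_record, random_dna, random_dot_bracket
from oracles import (
    single_linkage_heights, single_linkage_labels, tree_dist_oracle,
)


class TestEditDistance:
    @pytest.mark.parametrize("a,b,d", [
        ("ACGU", "ACGU", 0),
        ("ACGU", "AGU", 1),
        ("AAAA", "CCCC", 4),
        ("ACGT", "TGCA", 4),
        ("GATTACA", "GCATGCU", 4),
    ])
    def test_known_pairs(self, a, b, d):
        assert edit_distance(a, b) == d

    def test_metric_axioms_on_random_sample(self, rng):
        seqs = [random_dna(rng, int(rng.integers(4, 12))) for _ in range(12)]
        for a, b, c in itertools.combinations(seqs, 3):
            dab, dbc, dac = edit_distance(a, b), edit_distance(b, c), edit_distance(a, c)
            assert dab == edit_distance(b, a)
            assert dac <= dab + dbc
        for s in seqs:
            assert edit_distance(s, s) == 0

    def test_length_difference_lower_bound(self, rng):
        for _ in range(20):
            a = random_dna(rng, int(rng.integers(4, 14)))
            b = random_dna(rng, int(rng.integers(4, 14)))
            assert edit_distance(a, b) >= abs(len(a) - len(b))


class TestStructureTree:
    def test_all_dots(self):
        t = structure_to_tree("...")
        assert t.label == "R" and [c.label for c in t.children] == ["U", "U", "U"]

    def test_hairpin_chain(self):
        t = structure_to_tree("(.)")
        assert t.children[0].label == "P"
        assert t.children[0].children[0].label == "U"

    def test_nested_pairs(self):
        t = structure_to_tree("(())")
        assert t.children[0].label == "P" and t.children[0].children[0].label == "P"

    def test_node_count(self):
        dot = "((..))."
        assert structure_to_tree(dot).node_count == len(dot) - dot.count(")") + 1

    def test_unbalanced_raises(self):
        with pytest.raises(InputError):
            structure_to_tree("(()")


class TestTreeEditDistance:
    def test_identical_structures_of_different_sequences(self):
        assert structure_distance("((..))", "((..))") == 0

    def test_hairpin_vs_open(self):
        assert structure_distance("(.)", "...") == 3

    def test_matches_exhaustive_mapping_oracle(self, rng):
        for _ in range(60):
            d1 = random_dot_bracket(rng, 6)
            d2 = random_dot_bracket(rng, 6)
            t1, t2 = structure_to_tree(d1), structure_to_tree(d2)
            assert tree_edit_distance(t1, t2) == tree_dist_oracle(t1, t2)

    def test_metric_axioms(self, rng):
        dots = [random_dot_bracket(rng, 6) for _ in range(8)]
        trees = [structure_to_tree(d) for d in dots]
        for a, b, c in itertools.combinations(range(len(trees)), 3):
            dab = tree_edit_distance(trees[a], trees[b])
            dbc = tree_edit_distance(trees[b], trees[c])
            dac = tree_edit_distance(trees[a], trees[c])
            assert dab == tree_edit_distance(trees[b], trees[a])
            assert dac <= dab + dbc

    def test_node_count_lower_bound(self, rng):
        for _ in range(20):
            t1 = structure_to_tree(random_dot_bracket(rng, 6))
            t2 = structure_to_tree(random_dot_bracket(rng, 6))
            assert tree_edit_distance(t1, t2) >= abs(t1.node_count - t2.node_count)


def records_from(seqs, counts=None):
    counts = counts or {}
    return [make_record(i + 1, s, {1: counts.get(s, 3), 2: 3})
            for i, s in enumerate(seqs)]


class TestDistanceGraph:
    def test_identical_sequences_link_at_zero(self):
        recs = records_from(["AAAA"] * 3)
        # identical variable regions collapse in a real database, but the
        # graph must still handle duplicates (e.g. identical structures)
        recs[1].variable_region_dna = "AAAA"
        graph = build_distance_graph(recs, "edit", 1)
        assert sum(1 for d in graph.edges.values() if d == 0) == 3

    def test_distant_pairs_yield_no_edges(self):
        recs = records_from(["AAAAAAAA", "CCCCCCCC", "GGGGGGGG"])
        graph = build_distance_graph(recs, "edit", 2)
        assert graph.edges == {}

    def test_edges_match_full_matrix(self, rng):
        seqs = list({random_dna(rng, 6) for _ in range(25)})
        recs = records_from(seqs)
        d_max = 3
        graph = build_distance_graph(recs, "edit", d_max)
        for a, b in itertools.combinations(recs, 2):
            d = edit_distance(a.variable_region_dna, b.variable_region_dna)
            key = (min(a.id, b.id), max(a.id, b.id))
            if d <= d_max:
                assert graph.edges[key] == d
            else:
                assert key not in graph.edges

    def test_tree_metric_requires_structures(self):
        recs = records_from(["AAAA", "CCCC"])
        with pytest.raises(InputError, match="1"):
            build_distance_graph(recs, "tree", 3)


def graph_from_matrix(matrix) -> DistanceGraph:
    n = len(matrix)
    edges = {(i, j): int(matrix[i][j]) for i in range(n) for j in range(i + 1, n)}
    return DistanceGraph("edit", max(edges.values()), list(range(n)), edges)


def random_integer_matrix(rng, n, high=9):
    m = rng.integers(1, high, size=(n, n))
    m = np.triu(m, 1)
    return m + m.T


class TestComponents:
    def test_transitive_linking(self):
        recs = records_from(["AAAA", "AAAC", "AACC"])  # chain at distance 1
        graph = build_distance_graph(recs, "edit", 1)
        fams, singles = components_at_threshold(graph, 1)
        assert fams == [[1, 2, 3]] and singles == []

    def test_no_edges_all_singletons(self):
        recs = records_from(["AAAAAAAA", "CCCCCCCC"])
        graph = build_distance_graph(recs, "edit", 1)
        fams, singles = components_at_threshold(graph, 1)
        assert fams == [] and singles == [1, 2]

    def test_threshold_above_dmax_raises(self):
        graph = graph_from_matrix([[0, 2], [2, 0]])
        with pytest.raises(InputError):
            components_at_threshold(graph, 5)

    def test_matches_single_linkage_cut(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 20))
            m = random_integer_matrix(rng, n)
            graph = graph_from_matrix(m)
            for t in (1, 3, 5):
                fams, singles = components_at_threshold(graph, t)
                ours = {frozenset(f) for f in fams} | {frozenset([s]) for s in singles}
                labels = single_linkage_labels(m, t)
                theirs = {frozenset(np.flatnonzero(labels == l)) for l in set(labels)}
                assert ours == theirs

    def test_monotone_refinement(self, rng):
        m = random_integer_matrix(rng, 15)
        graph = graph_from_matrix(m)
        prev = None
        for t in range(1, int(m.max()) + 1):
            fams, singles = components_at_threshold(graph, t)
            parts = [set(f) for f in fams] + [{s} for s in singles]
            if prev is not None:
                for old in prev:
                    assert any(old <= new for new in parts)
            prev = parts


class TestDendrogram:
    def test_two_nodes(self):
        dendro = build_dendrogram(graph_from_matrix([[0, 3], [3, 0]]))
        assert dendro.merge_heights == [3] and dendro.complete

    def test_chain_merges_at_one(self):
        recs = records_from(["AAAA", "AAAC", "AACC"])
        graph = build_distance_graph(recs, "edit", 4)
        dendro = build_dendrogram(graph)
        assert dendro.merge_heights == [1, 1]

    def test_heights_match_single_linkage(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 15))
            m = random_integer_matrix(rng, n)
            dendro = build_dendrogram(graph_from_matrix(m))
            assert dendro.merge_heights == sorted(dendro.merge_heights)
            np.testing.assert_allclose(
                np.array(dendro.merge_heights, dtype=float),
                single_linkage_heights(m))

    def test_disconnected_graph_flagged_partial(self):
        graph = DistanceGraph("edit", 1, [0, 1, 2], {(0, 1): 1})
        dendro = build_dendrogram(graph)
        assert not dendro.complete and len(dendro.merges) == 1

    def test_newick_is_parseable(self):
        from io import StringIO

        from Bio import Phylo

        dendro = build_dendrogram(graph_from_matrix(
            [[0, 1, 4], [1, 0, 4], [4, 4, 0]]))
        tree = Phylo.read(StringIO(dendro.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["0", "1", "2"]


class TestFamilies:
    def test_roman_and_letter_labels(self):
        assert [roman_numeral(i) for i in (1, 4, 9, 13)] == ["I", "IV", "IX", "XIII"]
        assert [letter_label(i) for i in (1, 8, 26, 27)] == ["A", "H", "Z", "AA"]

    def test_two_families_far_apart_not_merged(self):
        fam1 = ["AAAAAAAAAA", "AAAAAAAAAC", "AAAAAAAAAG"]
        fam2 = ["GGGGGTTTTT", "GGGGGTTTTC", "GGGGGTTTTA"]
        recs = records_from(fam1 + fam2, {s: 100 for s in fam1})
        fams = call_sequence_families(recs)
        assert len(fams) == 2
        assert fams[0].label == "I" and set(fams[0].members) == {1, 2, 3}
        assert all(recs[i].sequence_family == "I" for i in range(3))

    def test_labels_follow_read_order(self):
        low = ["AAAAAAAAAA", "AAAAAAAAAC"]
        high = ["GGGGGTTTTT", "GGGGGTTTTC"]
        recs = records_from(low + high, {s: 500 for s in high})
        fams = call_sequence_families(recs)
        assert recs[2].sequence_family == "I"  # high-read family labelled first
        assert recs[0].sequence_family == "II"

    def test_identical_structures_one_family(self):
        recs = records_from(["AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG"])
        for r in recs:
            r.structure = StructureRecord("((....))..")
        fams = call_structure_families(recs)
        assert len(fams) == 1 and fams[0].label == "A"
        assert set(fams[0].members) == {1, 2, 3}

    def test_structure_family_growth_absorbs_singleton(self):
        # two structures at tree distance 0 (family) + one singleton within
        # reach at the high end of the range; family absorbs it
        recs = records_from(["A" * 10, "C" * 10, "G" * 10])
        recs[0].structure = StructureRecord("((....))..")
        recs[1].structure = StructureRecord("((....))..")
        recs[2].structure = StructureRecord("((.....)).")
        fams = call_structure_families(recs, threshold_range=(0, 6))
        assert len(fams) == 1 and 3 in fams[0].members

    def test_structure_family_growth_stops_at_other_family(self):
        recs = records_from(["A" * 10, "C" * 10, "G" * 10, "T" * 10],
                            {"A" * 10: 100, "C" * 10: 100})
        recs[0].structure = StructureRecord("((....))..")
        recs[1].structure = StructureRecord("((....))..")
        recs[2].structure = StructureRecord("..((....))")
        recs[3].structure = StructureRecord("..((....))")
        fams = call_structure_families(recs, threshold_range=(0, 6))
        assert len(fams) == 2
        assert {tuple(f.members) for f in fams} == {(1, 2), (3, 4)}

    def test_call_families_without_structures(self):
        recs = records_from(["AAAAAAAAAA", "AAAAAAAAAC"])
        seq_fams, struct_fams = call_families(recs, with_structures=False)
        assert len(seq_fams) == 1 and struct_fams == []
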