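"""Bipartite graph construction, connected components, groups and metrics."""

import networkx as nx
import numpy as np
import pytest

from proteofdr import pepgraph
from proteofdr.pepgraph import (
    MULTI_PROTEIN,
    SINGLE_PROTEIN,
    adjacency_from_incidence,
    ambiguity_metrics,
    build_incidence,
    connected_components,
    protein_groups,
    reduced_cc,
)

from helpers import dfs_protein_components, random_bipartite_pairs

TOY = [("p1", "A"), ("p2", "A"), ("p2", "B"), ("p3", "C")]


def _ccs(pairs):
    I = build_incidence(pairs)
    return connected_components(adjacency_from_incidence(I), I), I


class TestIncidence:
    def test_build_shape_and_membership(self):
        I = build_incidence(TOY)
        assert (len(I.peptides), len(I.proteins)) == (3, 3)
        assert I.matrix.sum() == 4

    def test_duplicate_pairs_deduplicated(self):
        I = build_incidence([("p1", "A"), ("p1", "A")])
        assert I.matrix.shape == (1, 1) and I.matrix.sum() == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_incidence([])

    def test_first_appearance_order(self):
        I = build_incidence(TOY)
        assert I.peptides == ["p1", "p2", "p3"]
        assert I.proteins == ["A", "B", "C"]


class TestAdjacency:
    def test_cross_product_hand_example(self):
        # p1 -> {A,B}, p2 -> {A}
        I = build_incidence([("p1", "A"), ("p1", "B"), ("p2", "A")])
        A = adjacency_from_incidence(I)
        assert A.matrix.toarray().tolist() == [[2, 1], [1, 1]]

    def test_no_sharing_gives_diagonal(self):
        I = build_incidence([("p1", "A"), ("p2", "B"), ("p3", "B")])
        A = adjacency_from_incidence(I).matrix.toarray()
        assert A.tolist() == [[1, 0], [0, 2]]

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            I = build_incidence(random_bipartite_pairs(rng))
            A = adjacency_from_incidence(I).matrix
            assert (A != A.T).nnz == 0
            assert (A.diagonal() >= 1).all()


class TestConnectedComponents:
    def test_toy_classification(self):
        ccs, _ = _ccs(TOY)
        by_prots = {frozenset(c.proteins): c for c in ccs}
        ab = by_prots[frozenset({"A", "B"})]
        assert ab.kind == MULTI_PROTEIN and set(ab.peptides) == {"p1", "p2"}
        c = by_prots[frozenset({"C"})]
        assert c.kind == SINGLE_PROTEIN and set(c.peptides) == {"p3"}

    def test_transitive_chain(self):
        ccs, _ = _ccs([("p", "A"), ("p", "B"), ("q", "B"), ("q", "C")])
        assert len(ccs) == 1 and set(ccs[0].proteins) == {"A", "B", "C"}

    def test_isolated_proteins(self):
        ccs, _ = _ccs([(f"p{i}", f"P{i}") for i in range(5)])
        assert len(ccs) == 5
        assert all(c.kind == SINGLE_PROTEIN for c in ccs)

    def test_partition_property(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            pairs = random_bipartite_pairs(rng)
            ccs, I = _ccs(pairs)
            prots = [p for c in ccs for p in c.proteins]
            assert sorted(prots) == sorted(I.proteins)
            # every peptide in exactly one CC
            peps = [p for c in ccs for p in c.peptides]
            assert sorted(peps) == sorted(I.peptides)

    def test_matches_dfs_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            pairs = random_bipartite_pairs(rng)
            ccs, _ = _ccs(pairs)
            assert {frozenset(c.proteins) for c in ccs} == dfs_protein_components(pairs)


class TestReducedStrategy:
    def test_toy_multi_only(self):
        I = build_incidence(TOY)
        out = reduced_cc(I)
        assert len(out) == 1
        assert set(out[0].proteins) == {"A", "B"}
        assert set(out[0].peptides) == {"p1", "p2"}

    def test_no_shared_peptides_empty(self):
        assert reduced_cc(build_incidence([("p1", "A"), ("p2", "B")])) == []

    def test_equals_multi_subset_of_full_computation(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            pairs = random_bipartite_pairs(rng)
            I = build_incidence(pairs)
            full = connected_components(adjacency_from_incidence(I), I)
            expected = {
                (frozenset(c.proteins), frozenset(c.peptides))
                for c in full
                if c.kind == MULTI_PROTEIN
            }
            got = {
                (frozenset(c.proteins), frozenset(c.peptides)) for c in reduced_cc(I)
            }
            assert got == expected


class TestProteinGroups:
    def test_identical_sets_grouped(self):
        I = build_incidence(
            [("p1", "A"), ("p2", "A"), ("p1", "B"), ("p2", "B"), ("p3", "C")]
        )
        groups = {frozenset(g.proteins): g.kind for g in protein_groups(I)}
        assert groups == {frozenset({"A", "B"}): "MULTI", frozenset({"C"}): "SINGLE"}

    def test_subset_is_not_equality(self):
        I = build_incidence([("p1", "A"), ("p2", "A"), ("p1", "B")])
        kinds = [g.kind for g in protein_groups(I)]
        assert kinds == ["SINGLE", "SINGLE"]

    def test_each_group_within_one_cc(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            pairs = random_bipartite_pairs(rng)
            I = build_incidence(pairs)
            ccs = connected_components(adjacency_from_incidence(I), I)
            cc_of = {p: i for i, c in enumerate(ccs) for p in c.proteins}
            for g in protein_groups(I):
                assert len({cc_of[p] for p in g.proteins}) == 1


class TestMetrics:
    def test_percentages_and_ratios(self):
        ccs, I = _ccs(TOY)
        m = ambiguity_metrics(ccs, I, gene_map={"A": "G1", "B": "G1", "C": "G2"})
        assert m.n_cc == 2
        assert m.pct_single_protein_cc == pytest.approx(50.0)
        # p1 and p3 specific of 3 peptides
        assert m.pct_specific_peptides == pytest.approx(100 * 2 / 3)
        assert m.protein_to_gene_ratios == [pytest.approx(2.0)]

    def test_unannotated_proteins_count_as_own_gene(self):
        ccs, I = _ccs([("p", "A"), ("p", "B"), ("q", "B"), ("q", "C"), ("r", "D")])
        m = ambiguity_metrics(ccs, I, gene_map={"A": "G1", "B": "G1"})
        assert m.protein_to_gene_ratios == [pytest.approx(3 / 2)]


class TestExport:
    def test_graphml_roundtrip_edges(self, tmp_path):
        ccs, I = _ccs(TOY)
        multi = next(c for c in ccs if c.kind == MULTI_PROTEIN)
        out = tmp_path / "cc.graphml"
        pepgraph.export_cc(multi, I, out, fmt="graphml")
        g = nx.read_graphml(out)
        assert {frozenset(e) for e in g.edges()} == {
            frozenset({"p1", "A"}),
            frozenset({"p2", "A"}),
            frozenset({"p2", "B"}),
        }
        kinds = nx.get_node_attributes(g, "kind")
        assert kinds["A"] == "protein" and kinds["p1"] == "peptide"

    def test_single_protein_cc_star_shape(self, tmp_path):
        ccs, I = _ccs([("p1", "A"), ("p2", "A"), ("p3", "A")])
        out = tmp_path / "cc.graphml"
        pepgraph.export_cc(ccs[0], I, out)
        g = nx.read_graphml(out)
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 3

    def test_dot_output_and_unknown_format(self, tmp_path):
        ccs, I = _ccs(TOY)
        out = tmp_path / "cc.dot"
        pepgraph.export_cc(ccs[0], I, out, fmt="dot")
        text = out.read_text()
        assert text.startswith("graph")
        assert ('"p1" -- "A"' in text) or ('"A" -- "p1"' in text)
        with pytest.raises(ValueError):
            pepgraph.export_cc(ccs[0], I, tmp_path / "x", fmt="svg")
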