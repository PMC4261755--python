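"""The similarity metric: matrix rows, the four factors, the combined score,
most-complete selection, and family sorting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cmapkit.bngl_io import parse_bngl
from cmapkit.contact_map import build_contact_map, edge_ids, matrix_row_ids
from cmapkit.similarity import (
    absolute_similarity,
    adjacency_matrix,
    matrix_rows,
    most_complete,
    shared_counts,
    shared_fractions,
    similarity_matrices,
    sort_family,
)
from cmapkit.synthetic_fixtures import FamilySpec, generate_family

from conftest import cmap_from


def _family(seed, **kw):
    texts, truth = generate_family(FamilySpec(seed=seed, **kw))
    return [build_contact_map(parse_bngl(t, n)) for t, n in zip(texts, truth.model_names)], truth


class TestMatrixRows:
    def test_states_replace_their_component(self):
        cmap = cmap_from("begin molecule types\nA(x,y~U~P)\nend molecule types\n")
        assert matrix_rows(cmap) == ["A.x#1", "A.y#1~P", "A.y#1~U"]

    def test_whole_molecule_component_is_a_row(self):
        cmap = cmap_from("begin molecule types\nB()\nend molecule types\n")
        assert matrix_rows(cmap) == ["B.B#1"]

    def test_flagship_model_row_count(self, egfr_cmap, egfr_model):
        n_states = sum(
            len(c.states) for mt in egfr_model.molecule_types for c in mt.components
        )
        n_stateless = sum(
            1 for mt in egfr_model.molecule_types for c in mt.components if not c.states
        )
        assert len(matrix_rows(egfr_cmap)) == n_states + n_stateless == 13

    def test_adjacency_matrix_rows_and_self_edge_diagonal(self):
        cmap = cmap_from(
            "begin reaction rules\n"
            "A(x) + A(x) -> A(x!1).A(x!1) k\n"
            "A(y~U) + B(s) -> A(y~U!1).B(s!1) k\n"
            "end reaction rules\n"
        )
        adj = adjacency_matrix(cmap)
        assert adj.row_ids == matrix_rows(cmap)
        i = adj.row_ids.index("A.x#1")
        assert adj.entries[i, i]  # homodimer self-edge on the diagonal
        j, k = adj.row_ids.index("A.y#1~U"), adj.row_ids.index("B.s#1")
        assert adj.entries[j, k] and adj.entries[k, j]
        assert np.array_equal(adj.entries, adj.entries.T)


class TestPairwise:
    def test_identity_counts(self, egfr_cmap):
        rows, edges = len(matrix_rows(egfr_cmap)), len(egfr_cmap.edges)
        assert shared_counts(egfr_cmap, egfr_cmap) == (rows, edges)
        assert shared_fractions(egfr_cmap, egfr_cmap) == (1.0, 1.0)
        assert absolute_similarity(egfr_cmap, egfr_cmap) == rows + edges

    def test_disjoint_models_share_nothing(self):
        a = cmap_from("begin reaction rules\nA(x) + B(y) -> A(x!1).B(y!1) k\nend reaction rules\n")
        b = cmap_from("begin reaction rules\nC(x) + D(y) -> C(x!1).D(y!1) k\nend reaction rules\n")
        assert shared_counts(a, b) == (0, 0)
        assert shared_fractions(a, b) == (0.0, 0.0)
        assert absolute_similarity(a, b) == 0.0

    def test_subgraph_scores_full_fractions_regardless_of_size(self, fceri_by_name):
        g = fceri_by_name["synthetic_fceri_fyn"]
        h = fceri_by_name["synthetic_fceri_fyn_trimer"]
        assert shared_fractions(g, h) == (1.0, 1.0)
        assert absolute_similarity(g, h) == len(matrix_rows(g)) + len(g.edges)

    def test_hand_evaluated_mixed_overlap(self):
        # A: rows {p,q,r,s,t} (5 stateless components), 4 edges
        a = cmap_from(
            "begin molecule types\nM(p,q,r,s,t)\nend molecule types\n"
            "begin reaction rules\n"
            "M(p) + M(q) -> M(p!1).M(q!1) k\n"
            "M(p) + M(r) -> M(p!1).M(r!1) k\n"
            "M(q) + M(s) -> M(q!1).M(s!1) k\n"
            "M(r) + M(t) -> M(r!1).M(t!1) k\n"
            "end reaction rules\n"
        )
        # B: larger — shares rows p,q,r,s and edges p-q, p-r only
        b = cmap_from(
            "begin molecule types\nM(p,q,r,s,u,v)\nN(w)\nend molecule types\n"
            "begin reaction rules\n"
            "M(p) + M(q) -> M(p!1).M(q!1) k\n"
            "M(p) + M(r) -> M(p!1).M(r!1) k\n"
            "M(u) + M(v) -> M(u!1).M(v!1) k\n"
            "M(s) + N(w) -> M(s!1).N(w!1) k\n"
            "end reaction rules\n"
        )
        assert shared_counts(a, b) == (4, 2)
        assert shared_fractions(a, b) == (4 / 5, 2 / 4)
        assert absolute_similarity(a, b) == pytest.approx(4 * 0.8 + 2 * 0.5)  # 4.2

    def test_zero_denominator_convention(self):
        no_edges = cmap_from("begin molecule types\nA(x)\nend molecule types\n")
        with_edges = cmap_from(
            "begin reaction rules\nA(x) + B(y) -> A(x!1).B(y!1) k\nend reaction rules\n"
        )
        nf, ef = shared_fractions(no_edges, with_edges)
        assert ef == 0.0 and nf == 1.0
        empty = cmap_from("")
        assert shared_fractions(empty, with_edges) == (0.0, 0.0)
        assert absolute_similarity(empty, with_edges) == 0.0

    @given(st.integers(0, 25))
    def test_symmetry(self, seed):
        cmaps, _ = _family(seed, n_models=3)
        for a in cmaps:
            for b in cmaps:
                assert shared_counts(a, b) == shared_counts(b, a)
                assert shared_fractions(a, b) == shared_fractions(b, a)
                assert absolute_similarity(a, b) == absolute_similarity(b, a)

    @given(st.integers(0, 25))
    def test_brute_force_oracle_on_small_maps(self, seed):
        """Nested O(n^2) identifier comparison agrees with shared_counts."""
        cmaps, _ = _family(
            seed,
            n_models=2,
            n_core_molecules=2,
            components_per_molecule=1,
            n_core_edges=1,
        )
        a, b = cmaps
        rows_a, rows_b = matrix_row_ids(a), matrix_row_ids(b)
        nodes = sum(1 for ra in rows_a for rb in rows_b if ra == rb)
        edges = sum(1 for ea in edge_ids(a) for eb in edge_ids(b) if ea == eb)
        assert shared_counts(a, b) == (nodes, edges)

    def test_monotonicity_adding_shared_element_never_decreases_score(self):
        core = (
            "begin reaction rules\n"
            "A(x) + B(y) -> A(x!1).B(y!1) k\n"
            "end reaction rules\n"
        )
        extra_a = "begin molecule types\nC(z)\nD(w)\nend molecule types\n"
        a0, b0 = cmap_from(core, "a"), cmap_from(core + extra_a, "b")
        base = absolute_similarity(a0, b0)
        shared_extra = "begin molecule types\nE(v)\nend molecule types\n"
        a1 = cmap_from(core + shared_extra, "a")
        b1 = cmap_from(core + extra_a + shared_extra, "b")
        assert absolute_similarity(a1, b1) >= base

    def test_monotonicity_growing_the_larger_model_never_raises_node_fraction(self):
        small = "begin molecule types\nA(x,y)\nend molecule types\n"
        large = "begin molecule types\nA(x,y,z)\nend molecule types\n"
        larger = "begin molecule types\nA(x,y,z)\nQ(r)\nend molecule types\n"
        s = cmap_from(small)
        nf_before, _ = shared_fractions(s, cmap_from(large))
        nf_after, _ = shared_fractions(s, cmap_from(larger))
        assert nf_after <= nf_before


class TestFamilyLevel:
    def test_single_model_matrices(self, egfr_cmap):
        mats = similarity_matrices([egfr_cmap])
        rows, edges = len(matrix_rows(egfr_cmap)), len(egfr_cmap.edges)
        assert mats.absolute.shape == (1, 1)
        assert mats.absolute[0, 0] == rows + edges
        assert mats.node_fraction[0, 0] == 1.0

    def test_identical_copies_give_constant_matrices(self, egfr_cmap):
        mats = similarity_matrices([egfr_cmap] * 3)
        for m in mats.as_dict().values():
            assert (m == m[0, 0]).all()

    @given(st.integers(0, 15))
    def test_matrices_equal_pairwise_calls(self, seed):
        cmaps, _ = _family(seed, n_models=5)
        mats = similarity_matrices(cmaps)
        for i in range(5):
            for j in range(5):
                ns, es = shared_counts(cmaps[i], cmaps[j])
                assert mats.shared_node_count[i, j] == ns
                assert mats.shared_edge_count[i, j] == es
                assert mats.absolute[i, j] == pytest.approx(
                    absolute_similarity(cmaps[i], cmaps[j])
                )
                assert mats.absolute[i, j] == mats.absolute[j, i]

    def test_most_complete_single_and_planted(self, egfr_cmap):
        assert most_complete([egfr_cmap]) == 0

    @given(st.integers(0, 25))
    def test_most_complete_matches_ground_truth(self, seed):
        cmaps, truth = _family(seed)
        assert most_complete(cmaps) == truth.most_complete

    def test_sort_identical_copies_ties_broken_by_name(self, egfr_cmap):
        import copy

        copies = []
        for name in ("zeta", "alpha", "mid"):
            c = copy.deepcopy(egfr_cmap)
            c.name = name
            copies.append(c)
        ordering = sort_family(copies)
        # reference = tie on size -> lexicographically first name ("alpha")
        assert copies[ordering.reference].name == "alpha"
        assert [copies[i].name for i in ordering.order] == ["alpha", "mid", "zeta"]

    def test_sort_supergraph_subgraph_disjoint(self):
        h = cmap_from(
            "begin molecule types\nA(x,y~U~P)\nB(s)\nend molecule types\n"
            "begin reaction rules\nA(x) + B(s) -> A(x!1).B(s!1) k\nend reaction rules\n",
            "h",
        )
        g = cmap_from("begin molecule types\nA(x,y~U~P)\nend molecule types\n", "g")
        d = cmap_from("begin molecule types\nZ(q)\nend molecule types\n", "d")
        ordering = sort_family([d, g, h])
        assert [("d", "g", "h")[i] for i in ordering.order] == ["h", "g", "d"]
        assert ordering.scores[1] == len(matrix_rows(g)) + len(g.edges)
        assert ordering.scores[2] == 0.0

    @given(st.integers(0, 15))
    def test_sort_invariant_under_input_shuffle(self, seed):
        cmaps, _ = _family(seed)
        names = [c.name for c in cmaps]
        base = [names[i] for i in sort_family(cmaps).order]
        shuffled = list(reversed(cmaps))
        again = [shuffled[i].name for i in sort_family(shuffled).order]
        assert again == base

    @given(st.integers(0, 15))
    def test_sort_scores_non_increasing_and_reference_first(self, seed):
        cmaps, _ = _family(seed)
        ordering = sort_family(cmaps)
        assert ordering.order[0] == ordering.reference
        tail = ordering.scores[1:]
        assert all(x >= y for x, y in zip(tail, tail[1:]))
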