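"""Contact-map construction, element identities, and structural statistics."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cmapkit.bngl_io import parse_bngl
from cmapkit.contact_map import (
    ElementIdError,
    build_contact_map,
    cmap_stats,
    element_ids,
    parse_element_id,
)
from cmapkit.synthetic_fixtures import FamilySpec, generate_family

from conftest import cmap_from


class TestBuildContactMap:
    def test_flagship_egfr_counts(self, egfr_cmap):
        """24 rules compress into 5 molecules, 6 edges, 3 modifiable components."""
        s = cmap_stats(egfr_cmap)
        assert s.n_molecules == 5
        assert s.n_edges == 6
        assert s.n_modifiable == 3

    def test_homodimer_rule_yields_self_edge(self):
        cmap = cmap_from(
            "begin reaction rules\nA(x) + A(x) -> A(x!1).A(x!1) k\nend reaction rules\n"
        )
        assert len(cmap.molecule_nodes) == 1
        assert [e.id for e in cmap.edges] == ["{A.x#1|A.x#1}"]

    def test_pure_state_change_marks_modifiable_without_edges(self):
        cmap = cmap_from(
            "begin reaction rules\nA(y~U) -> A(y~P) k\nend reaction rules\n"
        )
        assert cmap.edges == []
        node = cmap.component("A", "y", 1)
        assert node.modifiable
        assert node.state_nodes == ["U", "P"]

    def test_synthesis_alone_does_not_mark_modifiable(self):
        cmap = cmap_from(
            "begin reaction rules\n0 -> A(y~U) k\nend reaction rules\n"
        )
        assert not cmap.component("A", "y", 1).modifiable
        assert cmap.unstructured_nodes == {("syn", "A")}

    def test_degradation_and_reversible_synthesis_markers(self):
        cmap = cmap_from(
            "begin reaction rules\n"
            "A(x) -> 0 k\n"
            "0 <-> B(y) ks, kd\n"
            "end reaction rules\n"
        )
        assert cmap.unstructured_nodes == {("deg", "A"), ("syn", "B"), ("deg", "B")}

    def test_state_qualified_edge_distinct_from_unqualified(self):
        qualified = cmap_from(
            "begin reaction rules\nA(y~P) + B(s) -> A(y~P!1).B(s!1) k\nend reaction rules\n"
        )
        plain = cmap_from(
            "begin reaction rules\nA(y) + B(s) -> A(y!1).B(s!1) k\nend reaction rules\n"
        )
        assert [e.id for e in qualified.edges] == ["{A.y#1~P|B.s#1}"]
        assert [e.id for e in plain.edges] == ["{A.y#1|B.s#1}"]

    def test_wildcard_bond_sets_binds_but_no_edge(self):
        cmap = cmap_from(
            "begin reaction rules\nA(x!+,y~U) -> A(x!+,y~P) k\nend reaction rules\n"
        )
        assert cmap.edges == []
        assert cmap.component("A", "x", 1).binds

    def test_duplicate_rule_changes_only_contributing_rules(self):
        one = "A(x) + B(y) -> A(x!1).B(y!1) k\n"
        cmap1 = cmap_from(f"begin reaction rules\n{one}end reaction rules\n")
        cmap2 = cmap_from(f"begin reaction rules\n{one}{one}end reaction rules\n")
        assert element_ids(cmap1) == element_ids(cmap2)
        assert cmap2.edges[0].contributing_rules == {"R1", "R2"}

    def test_idempotent_and_unique_nodes_across_many_mentions(self, egfr_model):
        a = build_contact_map(egfr_model)
        b = build_contact_map(egfr_model)
        assert element_ids(a) == element_ids(b)
        # Grb2.SH2 is mentioned in many rules but is one node with one id
        assert sum(1 for e in element_ids(a) if e == "Grb2.SH2#1") == 1

    @given(st.integers(0, 40))
    def test_deleting_a_rule_never_adds_elements(self, seed):
        texts, truth = generate_family(FamilySpec(n_models=1, seed=seed))
        model = parse_bngl(texts[0], truth.model_names[0])
        full = element_ids(build_contact_map(model))
        for drop in range(len(model.rules)):
            pruned = parse_bngl(texts[0], "pruned")
            del pruned.rules[drop]
            assert element_ids(build_contact_map(pruned)) <= full


def _recount_from_parse_tree(model):
    """Independent element count straight off the parse tree."""
    n_molecules = len(model.molecule_types)
    n_components = sum(len(mt.components) for mt in model.molecule_types)
    n_states = sum(len(c.states) for mt in model.molecule_types for c in mt.components)
    edges = set()
    unstructured = set()
    for rule in model.rules:
        for side in ("reactants", "products"):
            tags = {}
            for pm in rule.molecules(side):
                for pc in pm.components:
                    if pc.bond not in ("none", "+", "?"):
                        tags.setdefault(pc.bond, []).append(
                            f"{pm.name}.{pc.name}#{pc.occurrence}"
                            + (f"~{pc.state}" if pc.state else "")
                        )
            for eps in tags.values():
                edges.add(tuple(sorted(eps)))
        if rule.is_synthesis:
            for pm in rule.molecules("products"):
                unstructured.add(("syn", pm.name))
                if rule.reversible:
                    unstructured.add(("deg", pm.name))
        if rule.is_degradation:
            for pm in rule.molecules("reactants"):
                unstructured.add(("deg", pm.name))
                if rule.reversible:
                    unstructured.add(("syn", pm.name))
    return n_molecules + n_components + n_states + len(edges) + len(unstructured)


class TestElementIds:
    def test_empty_model(self):
        assert element_ids(cmap_from("")) == set()

    def test_single_molecule_no_rules(self):
        cmap = cmap_from("begin molecule types\nA(x)\nend molecule types\n")
        assert element_ids(cmap) == {"A", "A.x#1"}

    @given(st.integers(0, 60))
    def test_cardinality_matches_parse_tree_recount(self, seed):
        texts, truth = generate_family(FamilySpec(seed=seed))
        for text, name in zip(texts, truth.model_names):
            model = parse_bngl(text, name)
            assert len(element_ids(build_contact_map(model))) == _recount_from_parse_tree(model)

    def test_ids_round_trip_through_the_grammar(self, egfr_cmap):
        kinds = {parse_element_id(eid)[0] for eid in element_ids(egfr_cmap)}
        assert kinds == {"molecule", "component", "state", "edge"}

    @pytest.mark.parametrize("bad", ["", "A.", "A.x", "A.x#0x", "{A.x#1}", "A.@born", "a b"])
    def test_malformed_ids_rejected(self, bad):
        with pytest.raises(ElementIdError):
            parse_element_id(bad)


class TestStats:
    def test_empty_model_all_zero(self):
        s = cmap_stats(cmap_from(""))
        assert (s.n_molecules, s.n_components, s.n_states, s.n_modifiable,
                s.n_edges, s.n_visual_nodes, s.n_matrix_rows) == (0,) * 7

    def test_fceri_family_edge_range(self, fceri_cmaps):
        for cmap in fceri_cmaps:
            assert 4 <= cmap_stats(cmap).n_edges <= 5

    def test_visual_node_convention(self, egfr_cmap):
        s = cmap_stats(egfr_cmap)
        assert s.n_visual_nodes == s.n_molecules + s.n_components + s.n_states + s.n_unstructured
        assert s.n_visual_nodes == 21

    @given(st.integers(0, 40))
    def test_planted_counts_recovered(self, seed):
        texts, truth = generate_family(FamilySpec(n_models=2, seed=seed))
        for i, (text, name) in enumerate(zip(texts, truth.model_names)):
            s = cmap_stats(build_contact_map(parse_bngl(text, name)))
            assert s.n_matrix_rows == len(truth.matrix_rows[i])
            assert s.n_edges == len(truth.edge_ids[i])
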