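"""Annotation, mapping suggestion, merging, lumping and cloning."""

import numpy as np
import pytest

import hemobond as hb
from hemobond.compose import (AmbiguityError, CompositionPlan, MappingProposal,
                              MergeError, annotate, auto_accept, clone, lump,
                              merge, suggest_mappings)
from hemobond.core import Bond, Component, Junction, Module, build_module
from hemobond.templates import VesselGeometry, make_segment


def seg(kind, name, **kw):
    return make_segment(kind, name, VesselGeometry(0.08, 0.007), **kw)


class TestAnnotate:
    def test_store_and_replace(self):
        m = seg("intermediate", "A")
        m = annotate(m, "A.vx1", "flow", "brachial_inlet")
        assert m.annotations["A.vx1"].entity_term == "brachial_inlet"
        m = annotate(m, "A.vx1", "flow", "radial_inlet")
        assert m.annotations["A.vx1"].entity_term == "radial_inlet"

    def test_unknown_variable(self):
        with pytest.raises(KeyError):
            annotate(seg("intermediate", "A"), "A.nope", "flow", "x")

    def test_vocabulary_is_closed(self):
        with pytest.raises(ValueError, match="vocabulary"):
            annotate(seg("intermediate", "A"), "A.vx1", "pressure", "x")

    def test_time_annotation_enables_unification(self):
        m = annotate(seg("intermediate", "A"), "t", "time", "t")
        assert m.annotations["t"].property_term == "time"


class TestSuggest:
    def test_exact_port_match(self):
        a = annotate(seg("intermediate", "A"), "A.vx1", "flow", "brachial")
        b = annotate(seg("intermediate", "B"), "B.j_in.v", "flow", "brachial")
        props = suggest_mappings(a, b)
        exact = [p for p in props if p.score == "exact" and p.source_var != "t"]
        assert len(exact) == 1
        assert (exact[0].source_var, exact[0].target_var) == ("A.vx1",
                                                              "B.j_in.v")
        assert exact[0].direction == "a"

    def test_no_shared_entities_gives_only_time(self):
        a = annotate(seg("intermediate", "A"), "A.vx1", "flow", "left")
        b = annotate(seg("intermediate", "B"), "B.j_in.v", "flow", "right")
        props = suggest_mappings(a, b)
        assert [p for p in props if p.score == "exact"] == [
            MappingProposal("t", "t", "exact", "a")]
        # property-only overlap remains visible as an advisory partial
        assert any(p.score == "partial" for p in props)

    def test_source_placeholder_mapping(self):
        # a waveform module's output flow maps onto the Sf placeholder
        a = annotate(seg("initial", "H"), "H.Sf.value", "flow",
                     "cardiac_output")
        b = seg("intermediate", "W")
        b = annotate(b, "W.j_in.v", "flow", "cardiac_output")
        props = [p for p in suggest_mappings(a, b)
                 if p.score == "exact" and p.source_var != "t"]
        assert props == [MappingProposal("H.Sf.value", "W.j_in.v", "exact",
                                         "a")]

    def test_sorted_exact_before_partial(self):
        a = annotate(seg("intermediate", "A"), "A.vx1", "flow", "m")
        a = annotate(a, "A.vx2", "flow", "x")
        b = annotate(seg("intermediate", "B"), "B.j_in.v", "flow", "m")
        props = suggest_mappings(a, b)
        scores = [p.score for p in props]
        assert scores == sorted(scores, key=lambda s: s != "exact")


def coupled_pair():
    a = annotate(seg("initial", "H"), "H.vx1", "flow", "aorta")
    b = annotate(seg("intermediate", "B"), "B.j_in.v", "flow", "aorta")
    return a, b


class TestMerge:
    def test_flow_mapping_binds_both_directions(self):
        a, b = coupled_pair()
        m = merge(a, b, auto_accept(a, b), name="pair")
        assert m.port("H.vx1").binding == "B.j_in.v"
        assert m.port("B.ux").binding == "H.j_out.u"
        bal_out = hb.junction_balance(m, "H.j_out")
        assert bal_out.balance.lhs.coeff(hb.core.var("B.j_in.v")) == -1
        bal_in = hb.junction_balance(m, "B.j_in")
        assert bal_in.balance.lhs.coeff(hb.core.var("H.j_out.u")) == 1

    def test_empty_accept_is_disjoint_union(self):
        a, b = coupled_pair()
        m = merge(a, b, [], name="both")
        assert all(p.binding is None for p in m.ports)
        assert len(m.components) == len(a.components) + len(b.components)

    def test_self_merge_needs_clone(self):
        a, _ = coupled_pair()
        with pytest.raises(MergeError, match="duplicate namespace"):
            merge(a, a, [], name="twice")
        doubled = merge(a, clone(a, "R_"), [], name="twice")
        assert len(doubled.components) == 2 * len(a.components)

    def test_double_binding_rejected(self):
        a, b = coupled_pair()
        prop = auto_accept(a, b)
        flow = [p for p in prop if p.source_var != "t"]
        with pytest.raises(MergeError, match="already bound"):
            merge(a, b, flow + flow, name="pair")

    def test_ambiguous_entities_rejected(self):
        a = annotate(seg("initial", "H"), "H.vx1", "flow", "aorta")
        a = annotate(a, "H.vx2", "flow", "aorta")
        b = annotate(seg("intermediate", "B"), "B.j_in.v", "flow", "aorta")
        with pytest.raises(AmbiguityError):
            auto_accept(a, b)


class TestLump:
    def test_toy_plan_runs_n_minus_1_merges(self, toy):
        modules, plan, _ = toy
        module, n_merges = lump(plan)
        assert n_merges == len(modules) - 1 == 4

    def test_seven_leaves_take_six_merges(self):
        # chain of 7 segments composed hierarchically
        spec = hb.TreeSpec(n_segments=7, max_branching=1, seed=11)
        modules, plan, _ = hb.random_tree(spec)
        _, n_merges = lump(plan)
        assert n_merges == 6

    def test_single_leaf_identity(self):
        m = seg("intermediate", "A")
        out, n_merges = lump(CompositionPlan.leaf(m))
        assert n_merges == 0 and out is m

    def test_port_bookkeeping(self, toy, toy_lumped):
        modules, _, geometry = toy
        total_ports = sum(len(m.ports) for m in modules.values())
        n_couplings = int(geometry["parent_id"].notna().sum())
        assert len(toy_lumped.exposed_ports) == total_ports - 2 * n_couplings

    def test_associativity_up_to_plan_shape(self, toy):
        """(A+B)+C and A+(B+C) give the same equations; element ids are
        namespaced once at construction, so no renaming is even needed."""
        modules, _, _ = toy
        chain = [modules["root"], modules["midA"], modules["midB"]]
        left = CompositionPlan.node(
            "L", [CompositionPlan.node("LL", [CompositionPlan.leaf(chain[0]),
                                              CompositionPlan.leaf(chain[1])]),
                  CompositionPlan.leaf(chain[2])])
        right = CompositionPlan.node(
            "R", [CompositionPlan.leaf(chain[0]),
                  CompositionPlan.node("RR", [CompositionPlan.leaf(chain[1]),
                                              CompositionPlan.leaf(chain[2])])])
        sa = hb.assemble_ode(lump(left)[0])
        sb = hb.assemble_ode(lump(right)[0])
        assert sa.states == sb.states
        for s in sa.states:
            np.testing.assert_allclose(sa.deriv_rows[s], sb.deriv_rows[s],
                                       rtol=1e-12, atol=1e-300)


class TestClone:
    def test_clone_is_structurally_identical(self, toy_lumped):
        c = clone(toy_lumped, "R_", lambda s: s.replace("left", "right"))
        assert len(c.components) == len(toy_lumped.components)
        assert c.element_ids.isdisjoint(toy_lumped.element_ids)
        assert all(e.startswith("R_") for e in c.element_ids)

    def test_clone_prefix_collision(self):
        m = build_module(
            "m",
            components=[Component("A.C", "C", 1e-9),
                        Component("p_A.C", "C", 1e-9)],
            junctions=[Junction("A.j", "zero")],
            bonds=[Bond("A.b", "A.j", "A.C"), Bond("p_A.b", "A.j", "p_A.C")])
        with pytest.raises(MergeError, match="collid"):
            clone(m, "p_")
        with pytest.raises(MergeError):
            clone(m, "")
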