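"""ODE assembly, linearity, closed-form limits and the energy audit."""

import numpy as np
import pytest
import sympy as sp
from scipy.linalg import expm

import hemobond as hb
from hemobond.core import Bond, Component, Junction, Port, build_module
from hemobond.odegen import (AssemblyError, assemble_ode, ode_to_json,
                             ode_to_text, power_audit)
from hemobond.templates import VesselGeometry, make_segment
from conftest import deriv_matrix


def reservoir(v0=2.5e-5):
    """Constant flow source charging a single compliance."""
    return build_module(
        "res",
        components=[Component("res.Sf", "Sf", v0),
                    Component("res.C", "C", 1e-9)],
        junctions=[Junction("res.j", "zero")],
        bonds=[Bond("res.bS", "res.Sf", "res.j"),
               Bond("res.bC", "res.j", "res.C")])


def windkessel(R=1.0186e5, C=1.306e-9, I=None, v0=1e-4):
    """Constant inflow into a compliance draining through R (and
    optionally an inertance) to a zero venous pressure."""
    comps = [Component("w.Sf", "Sf", v0),
             Component("w.C", "C", C),
             Component("w.R", "R", R),
             Component("w.Se", "Se", 0.0)]
    juncs = [Junction("w.j0", "zero"), Junction("w.j1", "one")]
    bonds = [Bond("w.bS", "w.Sf", "w.j0"),
             Bond("w.bC", "w.j0", "w.C"),
             Bond("w.b01", "w.j0", "w.j1"),
             Bond("w.bR", "w.j1", "w.R"),
             Bond("w.bSe", "w.j1", "w.Se")]
    if I is not None:
        comps.append(Component("w.I", "I", I))
        bonds.append(Bond("w.bI", "w.j1", "w.I"))
    return build_module("w", comps, juncs, bonds)


class TestAssembly:
    def test_single_compliance_constant_inflow(self):
        sys = assemble_ode(reservoir(v0=2.5e-5))
        assert sys.states == ["res.C.q"]
        assert float(sys.derivs["res.C.q"]) == pytest.approx(2.5e-5,
                                                             rel=1e-14)

    def test_intermediate_template_has_two_states(self):
        sys = assemble_ode(make_segment("intermediate", "A",
                                        VesselGeometry(0.1, 0.01)))
        assert sys.n_states == 2

    def test_state_count_equals_storage_count(self, toy_lumped, toy_system):
        n_storage = sum(1 for c in toy_lumped.components
                        if c.kind in ("C", "I"))
        assert toy_system.n_states == n_storage

    def test_coupled_pair_wall_flow_is_negative_sum(self):
        """After coupling, the upstream wall-branch flow equals the
        inflow minus the downstream draw: v* = -(-v_in) - v_child, the
        shared-junction relation of the two-module pair."""
        a = hb.annotate(make_segment("initial", "H", VesselGeometry(0.1, 0.01)),
                        "H.vx1", "flow", "aorta")
        b = hb.annotate(make_segment("intermediate", "B",
                                     VesselGeometry(0.08, 0.007)),
                        "B.j_in.v", "flow", "aorta")
        m = hb.merge(a, b, hb.auto_accept(a, b), name="pair")
        sys = assemble_ode(m)
        # at H.j_out: axial inflow - wall flow - bound port flow = 0
        lhs = sys.output_rows["H.b_wall_B.v"]
        rhs = (sys.output_rows["H.b_axis.v"] - sys.output_rows["B.j_in.v"])
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-300)

    def test_unbound_port_warning_and_neutrality(self):
        m = make_segment("intermediate", "A", VesselGeometry(0.1, 0.01))
        sys = assemble_ode(m)
        assert any("unbound" in w for w in sys.warnings)
        bare = build_module("A", m.components, m.junctions, m.bonds)
        sys_bare = assemble_ode(bare)
        assert sys.states == sys_bare.states
        np.testing.assert_array_equal(deriv_matrix(sys),
                                      deriv_matrix(sys_bare))

    def test_compliance_parallel_pressure_source_is_singular(self):
        m = build_module(
            "bad",
            components=[Component("bad.C", "C", 1e-9),
                        Component("bad.Se", "Se", 100.0)],
            junctions=[Junction("bad.j", "zero")],
            bonds=[Bond("bad.b1", "bad.j", "bad.C"),
                   Bond("bad.b2", "bad.j", "bad.Se")])
        with pytest.raises(AssemblyError, match="singular"):
            assemble_ode(m)

    def test_superposition(self, toy_system):
        """All-linear constitutive laws: the assembled right-hand side is
        linear, so doubling states and inputs doubles the derivatives."""
        A = deriv_matrix(toy_system)
        assert not np.any(A[:, 0])  # no constant term (Se = 0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=A.shape[1])
        x[0] = 0.0
        np.testing.assert_allclose(A @ (2 * x), 2 * (A @ x), rtol=1e-13)

    def test_exports(self, toy_system):
        text = ode_to_text(toy_system)
        assert "d(midA.I.v)/dt" in text
        import json
        doc = json.loads(ode_to_json(toy_system))
        assert set(doc["derivs"]) == set(toy_system.states)
        assert doc["outputs"]["root.j_out.u"]["terms"]


class TestClosedFormLimits:
    def test_rc_relaxation_to_R_v0(self):
        """First-order windkessel: u(t) = R v0 (1 - exp(-t/RC)); the
        inlet potential converges to R*v0 with time constant R*C."""
        R, C, v0 = 1.0186e5, 1.306e-9, 1e-4
        sys = assemble_ode(windkessel(R=R, C=C, v0=v0))
        tau = R * C
        res = hb.run(sys, t_end=20 * tau, output_dt=tau / 50,
                     rtol=1e-10, atol=1e-18)
        u = res["w.j0.u"]
        expected = R * v0 * (1 - np.exp(-res.t / tau))
        np.testing.assert_allclose(u, expected, rtol=3e-7,
                                   atol=1e-6 * R * v0)
        assert u[-1] == pytest.approx(R * v0, rel=1e-6)

    def test_ric_matches_matrix_exponential(self):
        """With the inertance included the step response follows the
        exact linear-system solution (matrix exponential oracle)."""
        R, C, I, v0 = 1.0186e5, 1.306e-9, 3.3423e5, 1e-4
        sys = assemble_ode(windkessel(R=R, C=C, I=I, v0=v0))
        rows = deriv_matrix(sys)
        c0, M = rows[:, 0], rows[:, 1:]
        t_end = 2.0
        res = hb.run(sys, t_end=t_end, output_dt=1e-2, rtol=1e-11, atol=1e-20)
        xeq = np.linalg.solve(M, -c0)
        for i, t in enumerate(res.t):
            x_exact = xeq + expm(M * t) @ (-xeq)
            for k, s in enumerate(sys.states):
                assert res[s][i] == pytest.approx(
                    x_exact[k], rel=1e-6, abs=1e-6 * max(abs(xeq).max(), 1e-30))


class TestPowerAudit:
    def test_consistent_run_conserves_energy(self, toy_system, toy_run):
        audit = power_audit(toy_system, toy_run)
        assert audit.max_relative <= 1e-8

    def test_perturbed_trace_flagged(self, toy_system, toy_run):
        traces = {k: np.array(v, copy=True) for k, v in toy_run.traces.items()}
        traces["root.b_axis.v"] = traces["root.b_axis.v"] * 1.1
        bad = hb.SimulationResult(toy_run.t, traces)
        audit = power_audit(toy_system, bad)
        assert audit.max_relative > 1e-3

    def test_zero_system_has_zero_residual(self):
        m = build_module(
            "z",
            components=[Component("z.Sf", "Sf", 0.0),
                        Component("z.R", "R", 1.0)],
            junctions=[Junction("z.j", "zero")],
            bonds=[Bond("z.b1", "z.Sf", "z.j"), Bond("z.b2", "z.j", "z.R")])
        sys = assemble_ode(m)
        res = hb.run(sys, t_end=0.1)
        audit = power_audit(sys, res)
        assert audit.max_residual == 0.0

    def test_missing_trace_is_mismatch(self, toy_system, toy_run):
        partial = hb.SimulationResult(toy_run.t,
                                      {"root.j_out.u":
                                       toy_run["root.j_out.u"]})
        with pytest.raises(hb.BondGraphError, match="mismatched"):
            power_audit(toy_system, partial)
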