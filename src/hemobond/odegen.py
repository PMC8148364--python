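"""Symbolic ODE assembly from a bond-graph module, plus the energy audit.

Every bond contributes two co-variables (u, v), every junction one
shared variable; the constitutive laws of R/C/I/Se/Sf and the junction
conservation relations form a square linear algebraic system in these
variables, with a right-hand side that is linear in the states (q per
compliance, v per inertance) and the time-function inputs.  Because all
parameters are bound numerically, the system is solved once with a
sparse LU factorisation over the basis ``[1, states..., inputs...]``;
the state derivatives and every junction/bond variable then come out as
explicit linear sympy expressions in states and inputs.  Algebraic
loops (e.g. resistor-only cycles) are handled by the same linear solve;
a structurally singular subsystem raises :class:`AssemblyError`.

States: ``q`` (m^3, excess volume) for each C with u = q/C and
dq/dt = flow into the compliance; ``v`` (m^3/s) for each I with
dv/dt = u/I.  Using the flow itself (rather than generalized momentum)
as the inertance state keeps traces directly comparable to reported
flows; the two are equivalent for linear I.

The energy audit re-evaluates the signed per-junction power sum
``sum_i u_i v_i`` (including bound-port contributions) on a stored
trajectory; junction conservation makes it vanish up to solver
tolerance, so a nonzero residual indicates an inconsistent trajectory
or a broken coupling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sps
import scipy.sparse.linalg as spla
import sympy as sp

from .core import BondGraphError, Module, bond_sign, port_sign, validate_module


class AssemblyError(BondGraphError):
    pass


@dataclass
class ODESystem:
    """Explicit linear ODE system assembled from a module."""

    module: Module
    states: list                 # ordered state names
    state_symbols: list
    derivs: dict                 # state name -> sympy expression
    outputs: dict                # variable name -> sympy expression
    inputs: list                 # time-function input names (Sf references)
    params: dict                 # component id -> numeric parameter
    warnings: list = field(default_factory=list)
    # numeric linear forms over the basis [1, states..., inputs...]; these
    # mirror `derivs`/`outputs` and exist so simulation and export scale
    # to large networks without symbolic coefficient extraction
    basis_names: list = field(default_factory=list)
    deriv_rows: dict = field(default_factory=dict)   # state -> coef row
    output_rows: dict = field(default_factory=dict)  # variable -> coef row

    @property
    def n_states(self) -> int:
        return len(self.states)


def _basis_expr(coefs, basis_syms, chop=0.0):
    """Linear sympy expression sum_k coefs[k] * basis_syms[k] (basis[0]=1)."""
    expr = sp.Integer(0)
    for c, s in zip(coefs, basis_syms):
        if c == 0.0:
            continue
        if chop and abs(c) < chop:
            continue
        expr += sp.Float(c, 17) * s if s is not None else sp.Float(c, 17)
    return expr


def assemble_ode(m: Module) -> ODESystem:
    """Assemble the explicit ODE system of a (validated) module.

    Unbound ports are treated as 0 and recorded as warnings, so an
    isolated module with ports runs exactly as its port-free twin.
    """
    # disconnected unions are mathematically fine (independent blocks)
    violations = [v for v in validate_module(m)
                  if v != "module graph is not connected"]
    if violations:
        raise AssemblyError("module does not validate: " + "; ".join(violations))

    warnings = [f"port {p.id} unbound; treated as 0" for p in m.exposed_ports]

    # ---- states and inputs (deterministic lexicographic order) ----------
    states, inputs, params = [], [], {}
    for c in m.components:
        if isinstance(c.param, (int, float)):
            params[c.id] = float(c.param)
        if c.kind in ("C", "I"):
            states.append(c.state_id)
        elif c.kind == "Sf" and isinstance(c.param, str) \
                and not c.param.startswith("external:"):
            if c.param not in inputs:
                inputs.append(c.param)
    states = sorted(states)
    inputs = sorted(inputs)
    state_syms = [sp.Symbol(s) for s in states]
    input_syms = [sp.Symbol(s) for s in inputs]
    basis_names = states + inputs          # basis[0] is the constant 1
    basis_index = {n: k + 1 for k, n in enumerate(basis_names)}
    n_basis = 1 + len(basis_names)
    basis_syms = [None] + state_syms + input_syms

    # ---- unknowns --------------------------------------------------------
    unames = []
    for b in sorted(m.bonds, key=lambda b: b.id):
        unames.append(f"{b.id}.u")
        unames.append(f"{b.id}.v")
    for j in sorted(m.junctions, key=lambda j: j.id):
        unames.append(j.common_var)
    uindex = {n: k for k, n in enumerate(unames)}
    n = len(unames)

    rows, cols, vals = [], [], []
    B = np.zeros((n, n_basis))
    comp_by_id = {c.id: c for c in m.components}
    junc_by_id = {j.id: j for j in m.junctions}
    eq = 0

    def coef(r, name, v):
        rows.append(r)
        cols.append(uindex[name])
        vals.append(float(v))

    # ---- endpoint relations (two per bond) -------------------------------
    for b in sorted(m.bonds, key=lambda b: b.id):
        for end in (b.tail, b.head):
            if end in junc_by_id:
                j = junc_by_id[end]
                covar = "u" if j.kind == "zero" else "v"
                coef(eq, f"{b.id}.{covar}", 1.0)
                coef(eq, j.common_var, -1.0)
            else:
                c = comp_by_id[end]
                s = 1.0 if b.head == c.id else -1.0  # power into component
                if c.kind == "R":
                    coef(eq, f"{b.id}.u", 1.0)
                    coef(eq, f"{b.id}.v", -c.param * s)
                elif c.kind == "C":
                    coef(eq, f"{b.id}.u", 1.0)
                    B[eq, basis_index[c.state_id]] = 1.0 / c.param
                elif c.kind == "I":
                    coef(eq, f"{b.id}.v", 1.0)
                    B[eq, basis_index[c.state_id]] = s
                elif c.kind == "Se":
                    coef(eq, f"{b.id}.u", 1.0)
                    B[eq, 0] = float(c.param)
                elif c.kind == "Sf":
                    coef(eq, f"{b.id}.v", 1.0)
                    if isinstance(c.param, (int, float)):
                        B[eq, 0] = -s * float(c.param)
                    elif c.param.startswith("external:"):
                        ref = c.param[len("external:"):]
                        if ref in uindex:
                            coef(eq, ref, s)
                        elif ref in basis_index:
                            B[eq, basis_index[ref]] = -s
                        else:
                            raise AssemblyError(
                                f"Sf {c.id}: unknown external reference {ref!r}")
                    else:
                        B[eq, basis_index[c.param]] = -s
                else:  # pragma: no cover
                    raise AssemblyError(f"unknown component kind {c.kind!r}")
            eq += 1

    # ---- junction conservation sums --------------------------------------
    for j in sorted(m.junctions, key=lambda j: j.id):
        bonds = m.bonds_at(j.id)
        if not bonds:
            raise AssemblyError(f"isolated junction {j.id!r}")
        covar = "v" if j.kind == "zero" else "u"
        for b in bonds:
            coef(eq, f"{b.id}.{covar}", float(bond_sign(b, j.id)))
        for p in m.ports_at(j.id):
            if p.binding is None:
                continue  # unbound port contributes exactly 0
            sgn = float(port_sign(p))
            if p.binding in uindex:
                coef(eq, p.binding, sgn)
            elif p.binding in basis_index:
                B[eq, basis_index[p.binding]] = -sgn
            else:
                raise AssemblyError(
                    f"port {p.id}: binding {p.binding!r} resolves to no "
                    "variable of this module")
        eq += 1

    if eq != n:
        raise AssemblyError(
            f"unbalanced algebraic system: {eq} equations, {n} unknowns")

    A = sps.csc_matrix((vals, (rows, cols)), shape=(n, n))
    try:
        lu = spla.splu(A)
    except RuntimeError as e:
        raise AssemblyError(f"singular algebraic subsystem: {e}") from e
    X = lu.solve(B)  # unknowns as rows of coefficients over the basis
    if not np.all(np.isfinite(X)):
        raise AssemblyError("singular algebraic subsystem (non-finite solve)")
    # two steps of iterative refinement: the solution coefficients then
    # satisfy A X = B to machine precision regardless of pivoting order,
    # so structurally equivalent builds (e.g. port-coupled vs directly
    # bonded) produce numerically identical dynamics
    for _ in range(2):
        R = B - A @ X
        if not np.any(R):
            break
        X = X + lu.solve(R)

    def expr_of(name):
        return _basis_expr(X[uindex[name]], basis_syms)

    # ---- state derivatives ------------------------------------------------
    derivs, deriv_rows = {}, {}
    bond_of_comp = {}
    for b in m.bonds:
        for end in (b.tail, b.head):
            if end in comp_by_id:
                bond_of_comp[end] = b
    for c in m.components:
        if c.kind not in ("C", "I"):
            continue
        b = bond_of_comp[c.id]
        s = 1.0 if b.head == c.id else -1.0
        if c.kind == "C":       # dq/dt = flow into the compliance
            row = s * X[uindex[f"{b.id}.v"]]
        else:                   # dv/dt = u / I
            row = X[uindex[f"{b.id}.u"]] / c.param
        derivs[c.state_id] = _basis_expr(row, basis_syms)
        deriv_rows[c.state_id] = row

    # ---- outputs: every junction and bond co-variable, plus states -------
    outputs, output_rows = {}, {}

    def put_output(name):
        row = X[uindex[name]]
        outputs[name] = _basis_expr(row, basis_syms)
        output_rows[name] = row

    for j in m.junctions:
        put_output(j.common_var)
    for b in m.bonds:
        put_output(f"{b.id}.u")
        put_output(f"{b.id}.v")
    for k, (s_name, s_sym) in enumerate(zip(states, state_syms)):
        outputs[s_name] = s_sym
        row = np.zeros(n_basis)
        row[1 + k] = 1.0
        output_rows[s_name] = row

    return ODESystem(module=m, states=states, state_symbols=state_syms,
                     derivs=derivs, outputs=outputs, inputs=inputs,
                     params=params, warnings=warnings,
                     basis_names=["1"] + basis_names,
                     deriv_rows=deriv_rows, output_rows=output_rows)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _row_terms(row, basis_names):
    """(const, {name: coef}) of a numeric coefficient row; basis[0] is 1."""
    const = float(row[0])
    terms = {n: float(c) for n, c in zip(basis_names[1:], row[1:]) if c != 0.0}
    return const, terms


def ode_to_text(sys: ODESystem) -> str:
    """Human-readable equation listing."""
    lines = [f"# ODE system of module {sys.module.name!r}",
             f"# states: {len(sys.states)}  inputs: {sys.inputs}"]
    for s in sys.states:
        lines.append(f"d({s})/dt = {sys.derivs[s]}")
    for k in sorted(sys.outputs):
        if k in sys.derivs or k in sys.states:
            continue
        lines.append(f"{k} = {sys.outputs[k]}")
    return "\n".join(lines) + "\n"


def ode_to_json(sys: ODESystem) -> str:
    """Machine-readable linear expression trees (JSON)."""
    doc = {"module": sys.module.name, "states": sys.states,
           "inputs": sys.inputs, "derivs": {}, "outputs": {}}
    for s in sys.states:
        const, terms = _row_terms(sys.deriv_rows[s], sys.basis_names)
        doc["derivs"][s] = {"const": const, "terms": terms}
    for k in sys.outputs:
        const, terms = _row_terms(sys.output_rows[k], sys.basis_names)
        doc["outputs"][k] = {"const": const, "terms": terms}
    return json.dumps(doc, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# energy audit
# ---------------------------------------------------------------------------

@dataclass
class PowerAudit:
    """Per-junction signed power residuals along a trajectory (J/s)."""

    residuals: dict              # junction id -> np.ndarray over time
    scales: dict                 # junction id -> max |u*v| term magnitude
    max_residual: float
    max_relative: float

    def ok(self, rel_tol: float = 1e-8) -> bool:
        return self.max_relative <= rel_tol


def power_audit(sys: ODESystem, traj) -> PowerAudit:
    """Evaluate the signed per-junction power sum on a stored trajectory.

    For a 0-junction the residual is ``sum sign(b) u_b v_b`` minus the
    bound-port outflow power ``u_j * v_bound``; dual for a 1-junction.
    Raises if the trajectory lacks a needed trace (mismatched run).
    """
    m = sys.module
    tr = traj.traces

    def trace(name):
        if name not in tr:
            raise BondGraphError(
                f"mismatched trajectory: trace {name!r} missing")
        return np.asarray(tr[name])

    residuals, scales = {}, {}
    max_res = 0.0
    max_rel = 0.0
    for j in m.junctions:
        res = None
        scale = 0.0
        for b in m.bonds_at(j.id):
            term = bond_sign(b, j.id) * trace(f"{b.id}.u") * trace(f"{b.id}.v")
            res = term if res is None else res + term
            scale = max(scale, float(np.max(np.abs(term), initial=0.0)))
        common = trace(j.common_var)
        for p in m.ports_at(j.id):
            if p.binding is None:
                continue
            term = port_sign(p) * common * trace(p.binding)
            res = res + term
            scale = max(scale, float(np.max(np.abs(term), initial=0.0)))
        if res is None:
            res = np.zeros(1)
        if not np.all(np.isfinite(res)):
            raise BondGraphError(f"non-finite power residual at {j.id}")
        residuals[j.id] = res
        scales[j.id] = scale
        r = float(np.max(np.abs(res), initial=0.0))
        max_res = max(max_res, r)
        if scale > 0:
            max_rel = max(max_rel, r / scale)
        elif r > 0:
            max_rel = np.inf
    return PowerAudit(residuals, scales, max_res, max_rel)
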