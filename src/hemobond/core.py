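"""Bond-graph data model and junction conservation algebra.

A bond graph reduces a physical system to components (here the one-port
elements R, C, I and the sources Se, Sf) exchanging power through bonds.
Each bond carries two co-variables — a potential ``u`` (pressure, J/m^3)
and a flow ``v`` (volumetric flow, m^3/s) — whose product is power.
Junctions impose the conservation laws: a 0-junction shares a common
potential and its flows sum to zero, a 1-junction shares a common flow
and its potentials sum to zero.

Modules additionally expose auxiliary *port* variables (``v_x`` on a
0-junction, ``u_x`` on a 1-junction).  A port is an extra, zero-defaulted
term in its junction's conservation sum; binding it to a variable of
another module couples the two modules exactly as adding a bond would,
while leaving the module definition itself immutable.

Sign convention: positive power flows tail -> head along a bond.  A bond
oriented into a junction contributes ``+`` to that junction's sum
equation, out of it ``-``.  Flow ports enter the 0-junction flow sum
with ``-`` (flow drawn off downstream); potential ports enter the
1-junction potential sum with ``+`` (upstream pressure driving the
inlet).  With this convention the classic coupled-pair relation
``v_A* = -v_A - v_B`` at a shared wall junction is reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import sympy as sp

COMPONENT_KINDS = ("R", "C", "I", "Se", "Sf")
JUNCTION_KINDS = ("zero", "one")
PORT_KINDS = ("flow", "potential")

#: units recorded per component kind (volume/pressure domain)
KIND_UNITS = {
    "R": "J.s.m-6",
    "C": "m6.J-1",
    "I": "J.s2.m-6",
    "Se": "J.m-3",
    "Sf": "m3.s-1",
}


class BondGraphError(Exception):
    """Base class for all construction/composition errors."""


class ModuleValidationError(BondGraphError):
    """Raised by :func:`build_module` when invariants are violated."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class Component:
    """One-port element: R (viscous resistance, u = R v), C (compliance,
    u = q/C), I (inertance, u = I dv/dt), Se (pressure source) or Sf
    (flow source; ``param`` may be a string naming a time function)."""

    id: str
    kind: str
    param: Union[float, str]
    units: str = ""
    state_id: Optional[str] = None

    def __post_init__(self):
        if self.kind in ("C", "I") and self.state_id is None:
            suffix = "q" if self.kind == "C" else "v"
            object.__setattr__(self, "state_id", f"{self.id}.{suffix}")
        if not self.units:
            object.__setattr__(self, "units", KIND_UNITS.get(self.kind, ""))


@dataclass(frozen=True)
class Junction:
    id: str
    kind: str  # "zero" (common potential) or "one" (common flow)

    @property
    def common_var(self) -> str:
        """Name of the shared co-variable: ``<id>.u`` or ``<id>.v``."""
        return f"{self.id}.u" if self.kind == "zero" else f"{self.id}.v"


@dataclass(frozen=True)
class Bond:
    """Directed power bond; positive power flows tail -> head."""

    id: str
    tail: str
    head: str


@dataclass(frozen=True)
class Port:
    """Auxiliary junction variable; unbound ports evaluate to 0."""

    id: str
    junction: str
    kind: str  # "flow" (on a zero-junction) or "potential" (on a one-junction)
    binding: Optional[str] = None


@dataclass(frozen=True)
class AnnotationTriple:
    """(variable, physical property, entity) metadata; the merge key."""

    variable: str
    property_term: str
    entity_term: str


@dataclass
class Module:
    """A named bond-graph network with exposed ports and annotations.

    All element ids are expected to be namespaced ``<segment>.<element>``
    once the module takes part in composition; templates do this on
    construction so merging never has to rename anything.
    """

    name: str
    components: list = field(default_factory=list)
    junctions: list = field(default_factory=list)
    bonds: list = field(default_factory=list)
    ports: list = field(default_factory=list)
    annotations: dict = field(default_factory=dict)  # variable -> AnnotationTriple

    # -- lookups -----------------------------------------------------------
    def component(self, cid: str) -> Component:
        return self._by_id(self.components, cid, "component")

    def junction(self, jid: str) -> Junction:
        return self._by_id(self.junctions, jid, "junction")

    def port(self, pid: str) -> Port:
        return self._by_id(self.ports, pid, "port")

    @staticmethod
    def _by_id(seq, eid, what):
        for e in seq:
            if e.id == eid:
                return e
        raise KeyError(f"unknown {what} id {eid!r}")

    @property
    def element_ids(self) -> set:
        return (
            {c.id for c in self.components}
            | {j.id for j in self.junctions}
            | {b.id for b in self.bonds}
            | {p.id for p in self.ports}
        )

    @property
    def exposed_ports(self) -> list:
        """Ports still unbound, i.e. available for coupling."""
        return [p for p in self.ports if p.binding is None]

    def bonds_at(self, jid: str) -> list:
        return [b for b in self.bonds if jid in (b.tail, b.head)]

    def ports_at(self, jid: str) -> list:
        return [p for p in self.ports if p.junction == jid]

    def variables(self) -> set:
        """Addressable variable names: junction common vars, per-bond
        co-variables, port variables, source values, states and time."""
        out = {"t"}
        for j in self.junctions:
            out.add(j.common_var)
        for b in self.bonds:
            out.add(f"{b.id}.u")
            out.add(f"{b.id}.v")
        for p in self.ports:
            out.add(p.id)
        for c in self.components:
            if c.kind in ("Se", "Sf"):
                out.add(f"{c.id}.value")
            if c.state_id:
                out.add(c.state_id)
            out.add(f"{c.id}.param")
        return out

    def copy(self) -> "Module":
        return Module(
            name=self.name,
            components=list(self.components),
            junctions=list(self.junctions),
            bonds=list(self.bonds),
            ports=list(self.ports),
            annotations=dict(self.annotations),
        )


# ---------------------------------------------------------------------------
# construction & validation
# ---------------------------------------------------------------------------

def validate_module(m: Module) -> list:
    """Return a list of human-readable invariant violations (empty if valid)."""
    violations = []
    seen = {}
    for group in (m.components, m.junctions, m.bonds, m.ports):
        for e in group:
            if e.id in seen:
                violations.append(f"duplicate id {e.id!r}")
            seen[e.id] = e

    comp_ids = {c.id for c in m.components}
    junc_ids = {j.id for j in m.junctions}

    for c in m.components:
        if c.kind not in COMPONENT_KINDS:
            violations.append(f"component {c.id}: unknown kind {c.kind!r}")
            continue
        if c.kind in ("R", "C", "I"):
            if not isinstance(c.param, (int, float)) or c.param <= 0:
                violations.append(f"component {c.id}: nonpositive parameter")
            if c.state_id is None and c.kind in ("C", "I"):
                violations.append(f"component {c.id}: missing state id")
        if c.kind in ("Se", "Sf") and c.state_id is not None:
            violations.append(f"component {c.id}: source carries no state")

    for j in m.junctions:
        if j.kind not in JUNCTION_KINDS:
            violations.append(f"junction {j.id}: unknown kind {j.kind!r}")

    endpoint_ids = comp_ids | junc_ids
    bond_count = {c: 0 for c in comp_ids}
    for b in m.bonds:
        for end in (b.tail, b.head):
            if end not in endpoint_ids:
                violations.append(f"bond {b.id}: dangling endpoint {end!r}")
            if end in bond_count:
                bond_count[end] += 1
    for cid, n in bond_count.items():
        if n > 1:
            violations.append(f"component {cid}: multiple bonds")
        elif n == 0:
            violations.append(f"component {cid}: no bond")

    for p in m.ports:
        if p.junction not in junc_ids:
            violations.append(f"port {p.id}: dangling junction {p.junction!r}")
            continue
        jkind = m.junction(p.junction).kind
        if p.kind == "flow" and jkind != "zero":
            violations.append(f"port {p.id}: port/junction mismatch "
                              "(flow port must attach to a zero-junction)")
        elif p.kind == "potential" and jkind != "one":
            violations.append(f"port {p.id}: port/junction mismatch "
                              "(potential port must attach to a one-junction)")
        elif p.kind not in PORT_KINDS:
            violations.append(f"port {p.id}: unknown kind {p.kind!r}")

    # connectivity: bonds and bound ports both count as couplings
    if m.junctions or m.components:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(comp_ids | junc_ids)
        for b in m.bonds:
            if b.tail in endpoint_ids and b.head in endpoint_ids:
                g.add_edge(b.tail, b.head)
        for p in m.ports:
            if p.binding and p.junction in junc_ids:
                owner = _variable_owner(m, p.binding)
                if owner:
                    g.add_edge(p.junction, owner)
        for c in m.components:
            if isinstance(c.param, str) and c.param.startswith("external:"):
                owner = _variable_owner(m, c.param[len("external:"):])
                if owner:
                    g.add_edge(c.id, owner)
        if g.number_of_nodes() and not nx.is_connected(g):
            violations.append("module graph is not connected")

    return violations


def _variable_owner(m: Module, variable: str):
    """Element id owning a namespaced variable (e.g. 'A.j_in.v' -> 'A.j_in'),
    or None if it cannot be resolved."""
    ids = m.element_ids
    if variable in ids:  # a port id
        try:
            return m.port(variable).junction
        except KeyError:
            return variable
    stem = variable.rsplit(".", 1)[0] if "." in variable else variable
    return stem if stem in ids else None


def build_module(name, components=(), junctions=(), bonds=(), ports=(),
                 annotations=None) -> Module:
    """Validate and return a :class:`Module`; raises on any violation."""
    m = Module(
        name=name,
        components=list(components),
        junctions=list(junctions),
        bonds=list(bonds),
        ports=list(ports),
        annotations=dict(annotations or {}),
    )
    violations = validate_module(m)
    if violations:
        raise ModuleValidationError(violations)
    return m


# ---------------------------------------------------------------------------
# junction conservation algebra
# ---------------------------------------------------------------------------

def var(name: str) -> sp.Symbol:
    """Sympy symbol for a namespaced variable name."""
    return sp.Symbol(name)


def bond_sign(b: Bond, jid: str) -> int:
    """+1 if the bond is oriented into junction ``jid``, -1 if out."""
    if b.head == jid:
        return 1
    if b.tail == jid:
        return -1
    raise ValueError(f"bond {b.id} does not touch junction {jid}")


def port_sign(p: Port) -> int:
    """Flow ports subtract from the 0-junction flow sum; potential ports
    add to the 1-junction potential sum (see module docstring)."""
    return -1 if p.kind == "flow" else 1


@dataclass(frozen=True)
class JunctionBalance:
    """Conservation relations at one junction: the co-variable equalities
    plus the signed sum equation (including port terms)."""

    junction: str
    kind: str
    equalities: tuple  # sympy Eq: bond co-variable == junction common var
    balance: sp.Eq     # signed sum == 0

    @property
    def equations(self):
        return list(self.equalities) + [self.balance]


def junction_balance(m: Module, j: Union[Junction, str]) -> JunctionBalance:
    """Symbolic conservation relations (common-variable equalities and the
    signed sum over bonds and ports) at junction ``j`` of module ``m``.

    For a 0-junction all bond potentials equal the junction potential and
    the signed bond flows plus port terms sum to zero; dually for a
    1-junction.  Unbound ports contribute exactly 0.
    """
    if isinstance(j, str):
        j = m.junction(j)
    bonds = m.bonds_at(j.id)
    if not bonds:
        raise BondGraphError(f"isolated junction {j.id!r}")

    shared, summed = ("u", "v") if j.kind == "zero" else ("v", "u")
    common = var(j.common_var)
    equalities = tuple(
        sp.Eq(var(f"{b.id}.{shared}"), common) for b in bonds
    )
    total = sp.Integer(0)
    for b in bonds:
        total += bond_sign(b, j.id) * var(f"{b.id}.{summed}")
    for p in m.ports_at(j.id):
        term = sp.Integer(0) if p.binding is None else var(p.binding)
        total += port_sign(p) * term
    return JunctionBalance(j.id, j.kind, equalities, sp.Eq(total, 0))


def power_residual(m: Module, j: Union[Junction, str]) -> sp.Expr:
    """Signed symbolic power sum ``sum_i u_i v_i`` at a junction, including
    bound port contributions; identically zero once the junction's
    equalities and balance are substituted (energy conservation)."""
    if isinstance(j, str):
        j = m.junction(j)
    expr = sp.Integer(0)
    for b in m.bonds_at(j.id):
        expr += bond_sign(b, j.id) * var(f"{b.id}.u") * var(f"{b.id}.v")
    common = var(j.common_var)
    for p in m.ports_at(j.id):
        if p.binding is not None:
            expr += port_sign(p) * common * var(p.binding)
    return expr
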