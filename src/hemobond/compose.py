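"""Semantic composition of bond-graph modules.

Modules are coupled without editing their internals: each carries
annotation triples (variable, physical property, entity term), and two
modules are merged by matching annotations and *binding* auxiliary
ports.  One accepted flow mapping performs the whole energy-consistent
join: the upstream flow port ``v_x`` is bound to the downstream inlet
common flow, and — automatically, as its reciprocal — the downstream
potential port ``u_x`` is bound to the upstream terminal common
potential.  Binding only one direction would couple mass transfer
without the matching pressure coupling and break energy conservation,
so the reciprocal is never left to the user.

The property vocabulary is closed: ``potential``, ``flow``, ``time`` or
``parameter:<name>``.  Entity terms are opaque strings (curated anatomy
identifiers); no ontology reasoning is attempted.

Hierarchical composition is expressed as a :class:`CompositionPlan`
tree whose leaves are modules; executing the plan (:func:`lump`) folds
it with n-1 pairwise merges for n leaves, auto-accepting the exact
annotation matches between each pair.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional

from .core import (AnnotationTriple, Bond, BondGraphError, Component,
                   Junction, Module, Port, validate_module)

PROPERTY_TERMS = ("potential", "flow", "time")


class MergeError(BondGraphError):
    pass


class AmbiguityError(MergeError):
    """Several candidate ports/variables share one entity term."""


def _check_property_term(term: str):
    if term in PROPERTY_TERMS or term.startswith("parameter:"):
        return
    raise ValueError(
        f"unknown property_term {term!r}; vocabulary is "
        "{potential, flow, time, parameter:<name>}")


def annotate(m: Module, variable: str, property_term: str,
             entity_term: str) -> Module:
    """Return a copy of ``m`` with the triple recorded on ``variable``;
    re-annotating a variable replaces its triple."""
    _check_property_term(property_term)
    if variable not in m.variables():
        raise KeyError(f"unknown variable {variable!r} in module {m.name!r}")
    out = m.copy()
    out.annotations[variable] = AnnotationTriple(variable, property_term,
                                                 entity_term)
    return out


@dataclass(frozen=True)
class MappingProposal:
    """Suggested identification of one variable in each module."""

    source_var: str   # variable in module a
    target_var: str   # variable in module b
    score: str        # "exact" or "partial"
    direction: str    # "a" or "b": which side is the port / source

    def sort_key(self):
        return (self.score != "exact", self.source_var, self.target_var)


def _is_coupling_var(m: Module, variable: str) -> bool:
    """True if the variable is a port or a source placeholder value."""
    if variable.endswith(".value"):
        return True
    try:
        m.port(variable)
        return True
    except KeyError:
        return False


def suggest_mappings(a: Module, b: Module) -> list:
    """Propose variable identifications between two annotated modules.

    Exact proposals pair identical (property, entity) annotations where
    exactly one side is a port or source placeholder; time variables are
    always proposed.  Partial proposals (advisory) pair a port/source
    with any same-property variable on the other side.  The list is
    sorted exact-before-partial, then lexicographically.
    """
    proposals = []
    seen = set()

    def add(src, tgt, score, direction):
        key = (src, tgt)
        if key not in seen:
            seen.add(key)
            proposals.append(MappingProposal(src, tgt, score, direction))

    # time is always unifiable
    add("t", "t", "exact", "a")

    ann_a = list(a.annotations.values())
    ann_b = list(b.annotations.values())
    for ta in ann_a:
        for tb in ann_b:
            if ta.property_term == "time" and tb.property_term == "time":
                continue  # covered by the implicit t<->t proposal
            if ta.property_term != tb.property_term:
                continue
            pa = _is_coupling_var(a, ta.variable)
            pb = _is_coupling_var(b, tb.variable)
            if pa == pb:
                continue  # exactly one side must be the coupling point
            direction = "a" if pa else "b"
            if ta.entity_term == tb.entity_term:
                add(ta.variable, tb.variable, "exact", direction)
            else:
                add(ta.variable, tb.variable, "partial", direction)

    proposals.sort(key=MappingProposal.sort_key)
    return proposals


def _owning_junction_of_flow_var(m: Module, variable: str) -> Junction:
    """Junction whose common flow is ``variable`` (a one-junction)."""
    for j in m.junctions:
        if j.common_var == variable:
            if j.kind != "one":
                raise MergeError(
                    f"{variable!r} is not a common-flow variable")
            return j
    raise MergeError(f"no junction owns flow variable {variable!r}")


def merge(a: Module, b: Module, accepted, name: str) -> Module:
    """Merge two modules into one by binding ports per accepted mappings.

    Each accepted *flow* mapping (upstream flow port <-> downstream
    common inlet flow) binds that port AND, reciprocally, binds the
    downstream module's potential port ``u_x`` (on the junction owning
    the inlet flow) to the upstream port's junction potential.  Source
    mappings rebind an Sf placeholder to the mapped flow variable.  Time
    mappings are no-ops (time is global).  Unbound ports stay exposed.
    """
    overlap = a.element_ids & b.element_ids
    if overlap:
        raise MergeError(
            f"duplicate namespace: shared element ids {sorted(overlap)[:5]} "
            "(clone with a prefix before merging a module with itself)")

    merged = Module(
        name=name,
        components=list(a.components) + list(b.components),
        junctions=list(a.junctions) + list(b.junctions),
        bonds=list(a.bonds) + list(b.bonds),
        ports=list(a.ports) + list(b.ports),
        annotations={**a.annotations, **b.annotations},
    )

    def bind_port(pid: str, target: str):
        for i, p in enumerate(merged.ports):
            if p.id == pid:
                if p.binding is not None:
                    raise MergeError(f"port {pid!r} already bound")
                merged.ports[i] = dataclasses.replace(p, binding=target)
                return p
        raise MergeError(f"unknown port {pid!r}")

    def rebind_source(cid_value: str, target: str):
        cid = cid_value[: -len(".value")]
        for i, c in enumerate(merged.components):
            if c.id == cid:
                if c.kind != "Sf":
                    raise MergeError(
                        f"only Sf placeholders can be rebound, not {c.kind}")
                merged.components[i] = dataclasses.replace(
                    c, param=f"external:{target}")
                return
        raise MergeError(f"unknown source component {cid!r}")

    for prop in accepted:
        if prop.source_var == "t" and prop.target_var == "t":
            continue
        side_port, side_other = (a, b) if prop.direction == "a" else (b, a)
        port_var = prop.source_var if prop.direction == "a" else prop.target_var
        other_var = prop.target_var if prop.direction == "a" else prop.source_var

        if port_var.endswith(".value"):
            rebind_source(port_var, other_var)
            continue
        try:
            port = side_port.port(port_var)
        except KeyError:
            raise MergeError(
                f"incompatible proposal: {port_var!r} is not a port of "
                f"module {side_port.name!r}")

        if port.kind == "flow":
            bind_port(port.id, other_var)
            # reciprocal: downstream u_x <- upstream junction potential
            upstream_j = side_port.junction(port.junction)
            inlet_j = _owning_junction_of_flow_var(side_other, other_var)
            ux = [p for p in side_other.ports_at(inlet_j.id)
                  if p.kind == "potential"]
            if len(ux) > 1:
                raise AmbiguityError(
                    f"junction {inlet_j.id!r} exposes several potential ports")
            if ux:
                bind_port(ux[0].id, upstream_j.common_var)
        elif port.kind == "potential":
            bind_port(port.id, other_var)
        else:  # pragma: no cover - kinds are validated at build time
            raise MergeError(f"unknown port kind {port.kind!r}")

    # a merge with no accepted couplings is a legitimate disjoint union
    # (shares only time), so connectivity is not enforced here
    violations = [v for v in validate_module(merged)
                  if v != "module graph is not connected"]
    if violations:
        raise MergeError("merge produced invalid module: " + "; ".join(violations))
    return merged


def auto_accept(a: Module, b: Module) -> list:
    """Exact proposals between two modules, with ambiguity detection:
    if one entity term yields several exact proposals the merge cannot
    be decided automatically and an :class:`AmbiguityError` is raised."""
    exact = [p for p in suggest_mappings(a, b) if p.score == "exact"]
    by_var = {}
    for p in exact:
        if p.source_var == "t":
            continue
        for v in (("a", p.source_var), ("b", p.target_var)):
            if v in by_var:
                raise AmbiguityError(
                    f"variable {v[1]!r} matched by several exact proposals; "
                    "refine entity terms or accept mappings manually")
            by_var[v] = p
    return exact


@dataclass
class CompositionPlan:
    """Ordered merge tree; leaves are modules, internal nodes lumped
    sub-networks.  n leaves imply n-1 pairwise merges."""

    name: str
    children: list = field(default_factory=list)  # CompositionPlan | Module
    module: Optional[Module] = None               # set on leaves

    @property
    def is_leaf(self) -> bool:
        return self.module is not None

    def leaves(self) -> list:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    @classmethod
    def leaf(cls, module: Module) -> "CompositionPlan":
        return cls(name=module.name, module=module)

    @classmethod
    def node(cls, name: str, children) -> "CompositionPlan":
        return cls(name=name, children=list(children))


def lump(plan: CompositionPlan, accepted_resolver: Callable = auto_accept):
    """Execute a composition plan depth-first left-to-right.

    Returns ``(module, n_merges)``; ``n_merges`` equals the number of
    leaves minus one.  Merge errors propagate annotated with the plan
    path.  A single-leaf plan is the identity.
    """
    counter = {"merges": 0}

    def run(node: CompositionPlan, path: str) -> Module:
        if node.is_leaf:
            return node.module
        if not node.children:
            raise MergeError(f"empty plan node at {path}")
        parts = [run(c, f"{path}/{c.name}") for c in node.children]
        acc = parts[0]
        for nxt in parts[1:]:
            try:
                mappings = accepted_resolver(acc, nxt)
                acc = merge(acc, nxt, mappings,
                            name=node.name if nxt is parts[-1]
                            else f"{node.name}+")
            except BondGraphError as e:
                raise MergeError(f"at plan node {path}: {e}") from e
            counter["merges"] += 1
        # the intermediate fold names all collapse to the node name
        acc.name = node.name
        return acc

    result = run(plan, plan.name)
    return result, counter["merges"]


def clone(m: Module, prefix: str,
          entity_renamer: Callable[[str], str] = lambda s: s) -> Module:
    """Deep copy with every element id prefixed and entity terms rewritten.

    Used to reuse a lumped module for a symmetric structure (e.g. the
    contralateral limb).  Raises on id collisions with the prefix.
    """
    if not prefix:
        raise MergeError("clone prefix must be non-empty (id collision)")

    def rn(eid: str) -> str:
        return f"{prefix}{eid}"

    new_ids = {rn(e) for e in m.element_ids}
    if new_ids & m.element_ids:
        raise MergeError(f"clone prefix {prefix!r} collides with existing ids")

    def rn_var(vname: str) -> str:
        # variables are '<element id>.<suffix>' or a bare port id or 't'
        if vname == "t":
            return "t"
        return rn(vname)

    comps = []
    for c in m.components:
        param = c.param
        if isinstance(param, str) and param.startswith("external:"):
            param = "external:" + rn_var(param[len("external:"):])
        comps.append(Component(rn(c.id), c.kind, param, c.units,
                               rn(c.state_id) if c.state_id else None))
    juncs = [Junction(rn(j.id), j.kind) for j in m.junctions]
    bonds = [Bond(rn(b.id), rn(b.tail), rn(b.head)) for b in m.bonds]
    ports = [Port(rn(p.id), rn(p.junction), p.kind,
                  rn_var(p.binding) if p.binding else None)
             for p in m.ports]
    annotations = {}
    for v, tr in m.annotations.items():
        nv = rn_var(v)
        annotations[nv] = AnnotationTriple(nv, tr.property_term,
                                           entity_renamer(tr.entity_term))
    out = Module(f"{prefix}{m.name}", comps, juncs, bonds, ports, annotations)
    return out
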