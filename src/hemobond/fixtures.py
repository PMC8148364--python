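"""Synthetic vessel networks: deterministic toy tree, seeded random
trees, geometry-table builders, a monolithic (single-module) oracle
construction, and a synthetic seven-subdivision whole-body plan.

Everything here is generated programmatically so the rest of the
package is testable without any external geometry.  The random trees
use a fixed parent/child radius ratio (default 0.8) rather than a
physiological branching law — the fixture only needs plausible
stiffness ratios, not measured anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .compose import CompositionPlan, annotate, clone
from .core import Bond, Module, validate_module, ModuleValidationError
from .templates import (DEFAULT_BRANCH_PORTS, VesselGeometry,
                        VesselProperties, make_segment)

GEOMETRY_COLUMNS = ["segment_id", "kind", "length_m", "radius_m", "parent_id"]


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of a randomized vessel tree."""

    n_segments: int
    max_branching: int = 2
    seed: int = 0
    root_radius: float = 0.01       # m
    radius_ratio: float = 0.8       # child radius / parent radius
    length_ratio: float = 10.0      # segment length / radius

    def __post_init__(self):
        if self.n_segments < 2:
            raise ValueError("need at least 2 segments (initial + terminal)")
        if self.max_branching < 1:
            raise ValueError("max_branching must be >= 1")


# ---------------------------------------------------------------------------
# geometry tables
# ---------------------------------------------------------------------------

def geometry_table(rows) -> pd.DataFrame:
    """Rows of (segment_id, kind, length_m, radius_m, parent_id)."""
    df = pd.DataFrame(rows, columns=GEOMETRY_COLUMNS)
    return df


def save_geometry(geometry: pd.DataFrame, path) -> None:
    geometry.to_csv(path, sep="\t", index=False)


def load_geometry(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"segment_id": str, "kind": str, "parent_id": str})
    df["parent_id"] = df["parent_id"].where(df["parent_id"].notna(), None)
    return df


def entity_term(parent: str, child: str) -> str:
    """Entity naming the anatomical junction between two segments."""
    return f"{parent}:{child}"


def segments_from_geometry(geometry: pd.DataFrame,
                           props: VesselProperties = VesselProperties(),
                           **options) -> dict:
    """Instantiate one annotated template module per geometry row.

    Each parent's k-th auxiliary flow port and the corresponding
    child's inlet common flow are annotated with the same entity term,
    so composition needs no further curation.
    """
    modules = {}
    children = {}
    for row in geometry.itertuples(index=False):
        children.setdefault(row.parent_id, []).append(row.segment_id)
    for row in geometry.itertuples(index=False):
        m = make_segment(row.kind, row.segment_id,
                         VesselGeometry(l=row.length_m, r=row.radius_m),
                         props, **options)
        modules[row.segment_id] = m

    nports = options.get("n_branch_ports", DEFAULT_BRANCH_PORTS)
    for parent, kids in children.items():
        if parent is None:
            continue
        if len(kids) > nports:
            raise ModuleValidationError(
                [f"segment {parent}: {len(kids)} children exceed "
                 f"{nports} branch ports"])
        for k, child in enumerate(kids, start=1):
            term = entity_term(parent, child)
            modules[parent] = annotate(modules[parent], f"{parent}.vx{k}",
                                       "flow", term)
            modules[child] = annotate(modules[child], f"{child}.j_in.v",
                                      "flow", term)
    return modules


def plan_from_geometry(geometry: pd.DataFrame, modules: dict,
                       name: str = "network") -> CompositionPlan:
    """Flat left-fold plan in topological (parents-first) order, so every
    intermediate merge is connected."""
    order = _topological_order(geometry)
    return CompositionPlan.node(
        name, [CompositionPlan.leaf(modules[s]) for s in order])


def _topological_order(geometry: pd.DataFrame) -> list:
    parent = dict(zip(geometry["segment_id"], geometry["parent_id"]))
    placed, order = set(), []
    pending = list(geometry["segment_id"])
    while pending:
        rest = []
        for s in pending:
            p = parent[s]
            if p is None or p in placed:
                order.append(s)
                placed.add(s)
            else:
                rest.append(s)
        if len(rest) == len(pending):
            raise ValueError("geometry table has a parent cycle or gap")
        pending = rest
    return order


def monolithic_from_geometry(geometry: pd.DataFrame,
                             props: VesselProperties = VesselProperties(),
                             name: str = "monolithic",
                             **options) -> Module:
    """Build the whole network directly as one module, wiring parent
    outlets to child inlets with real bonds.  This is the independent
    construction against which plan-composed networks are compared;
    template ports are kept but stay unbound (they contribute 0)."""
    segs = {}
    for row in geometry.itertuples(index=False):
        segs[row.segment_id] = make_segment(
            row.kind, row.segment_id,
            VesselGeometry(l=row.length_m, r=row.radius_m), props, **options)
    m = Module(name)
    for s in _topological_order(geometry):
        seg = segs[s]
        m.components += seg.components
        m.junctions += seg.junctions
        m.bonds += seg.bonds
        m.ports += seg.ports
    for row in geometry.itertuples(index=False):
        if row.parent_id is None:
            continue
        m.bonds.append(Bond(f"couple.{row.parent_id}.{row.segment_id}",
                            f"{row.parent_id}.j_out",
                            f"{row.segment_id}.j_in"))
    bad = validate_module(m)
    if bad:
        raise ModuleValidationError(bad)
    return m


# ---------------------------------------------------------------------------
# fixed toy network
# ---------------------------------------------------------------------------

def toy_tree(props: VesselProperties = VesselProperties(), **options):
    """Fixed 5-segment tree: initial root (r = 0.01 m, l = 0.1 m), a
    bifurcating and a plain intermediate (r = 0.007 m, l = 0.08 m) and
    two terminals (r = 0.005 m, l = 0.05 m); fully annotated.

    Returns ``(modules, plan, geometry)``; identical on every call.
    """
    geometry = geometry_table([
        ("root", "initial", 0.1, 0.01, None),
        ("midA", "intermediate", 0.08, 0.007, "root"),
        ("midB", "intermediate", 0.08, 0.007, "midA"),
        ("termA", "terminal", 0.05, 0.005, "midA"),
        ("termB", "terminal", 0.05, 0.005, "midB"),
    ])
    modules = segments_from_geometry(geometry, props, **options)
    plan = plan_from_geometry(geometry, modules, name="toy")
    return modules, plan, geometry


# ---------------------------------------------------------------------------
# randomized trees
# ---------------------------------------------------------------------------

def random_tree(spec: TreeSpec,
                props: VesselProperties = VesselProperties(), **options):
    """Seed-reproducible random tree honouring ``max_branching``.

    The root is an initial segment, leaves are terminals, interior
    nodes intermediates; radii shrink by ``radius_ratio`` per
    generation and lengths follow ``length_ratio * r``.  Returns
    ``(modules, plan, geometry)``.
    """
    nports = options.get("n_branch_ports", DEFAULT_BRANCH_PORTS)
    if spec.max_branching > nports:
        raise ValueError(
            f"max_branching = {spec.max_branching} exceeds the template's "
            f"{nports} branch ports")
    rng = np.random.default_rng(spec.seed)
    parent = {0: None}
    n_children = {0: 0}
    for i in range(1, spec.n_segments):
        candidates = [k for k in parent if n_children[k] < spec.max_branching]
        if not candidates:
            raise ValueError(
                "n_segments unreachable under max_branching constraint")
        p = int(rng.choice(candidates))
        parent[i] = p
        n_children[p] += 1
        n_children[i] = 0

    depth = {0: 0}
    for i in range(1, spec.n_segments):
        depth[i] = depth[parent[i]] + 1

    rows = []
    for i in range(spec.n_segments):
        if i == 0:
            kind = "initial"
        elif n_children[i] == 0:
            kind = "terminal"
        else:
            kind = "intermediate"
        r = spec.root_radius * spec.radius_ratio ** depth[i]
        rows.append((f"s{i:02d}", kind, spec.length_ratio * r, r,
                     None if parent[i] is None else f"s{parent[i]:02d}"))
    geometry = geometry_table(rows)
    modules = segments_from_geometry(geometry, props, **options)
    plan = plan_from_geometry(geometry, modules,
                              name=f"random_{spec.seed}")
    return modules, plan, geometry


# ---------------------------------------------------------------------------
# synthetic whole-body plan (seven lumped subdivisions)
# ---------------------------------------------------------------------------

ADAN_SUBDIVISIONS = ("heart", "trunk", "head_and_neck", "left_arm",
                     "right_arm", "left_leg", "right_leg")


def adan_plan(props: VesselProperties = VesselProperties(), **options):
    """Hierarchical whole-body composition plan with the seven lumped
    subdivisions of the open-loop systemic arterial tree: head and
    neck, heart (cardiac output), trunk, and the four limbs, the right
    limbs being clones of the left ones (symmetric-limb reuse).

    The per-subdivision segment chains are SYNTHETIC stand-ins (the
    true 86-segment topology is external, optional data); the
    subdivision structure itself is the real one.  Returns
    ``(plan, geometry)`` where the geometry covers the directly built
    (non-cloned) segments.
    """
    geometry = geometry_table([
        ("heart_aorta", "initial", 0.04, 0.012, None),
        ("trunk_1", "intermediate", 0.06, 0.011, "heart_aorta"),
        ("trunk_2", "intermediate", 0.08, 0.010, "trunk_1"),
        ("trunk_3", "intermediate", 0.08, 0.009, "trunk_2"),
        ("neck_1", "intermediate", 0.05, 0.004, "trunk_1"),
        ("head_1", "terminal", 0.04, 0.003, "neck_1"),
        ("left_arm_1", "intermediate", 0.08, 0.0045, "trunk_2"),
        ("left_arm_2", "terminal", 0.06, 0.003, "left_arm_1"),
        ("left_leg_1", "intermediate", 0.10, 0.006, "trunk_3"),
        ("left_leg_2", "terminal", 0.08, 0.004, "left_leg_1"),
    ])
    modules = segments_from_geometry(geometry, props, **options)

    def mirror(seg_names, attach_parent, attach_port):
        renamer = lambda s: s.replace("left", "right")
        cloned = [clone(modules[s], "mirror_", renamer) for s in seg_names]
        modules[attach_parent] = annotate(
            modules[attach_parent], f"{attach_parent}.{attach_port}", "flow",
            entity_term(attach_parent,
                        seg_names[0].replace("left", "right")))
        return cloned

    right_arm = mirror(["left_arm_1", "left_arm_2"], "trunk_2", "vx3")
    right_leg = mirror(["left_leg_1", "left_leg_2"], "trunk_3", "vx2")

    leaf = CompositionPlan.leaf
    node = CompositionPlan.node
    plan = node("adan_open_loop", [
        node("heart", [leaf(modules["heart_aorta"])]),
        node("trunk", [leaf(modules["trunk_1"]), leaf(modules["trunk_2"]),
                       leaf(modules["trunk_3"])]),
        node("head_and_neck", [leaf(modules["neck_1"]),
                               leaf(modules["head_1"])]),
        node("left_arm", [leaf(modules["left_arm_1"]),
                          leaf(modules["left_arm_2"])]),
        node("right_arm", [leaf(c) for c in right_arm]),
        node("left_leg", [leaf(modules["left_leg_1"]),
                          leaf(modules["left_leg_2"])]),
        node("right_leg", [leaf(c) for c in right_leg]),
    ])
    return plan, geometry
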