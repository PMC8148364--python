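"""Vessel segment parameters and the three bond-graph segment templates.

A straight vessel segment of length ``l`` and radius ``r`` filled with
blood of viscosity ``nu`` and density ``rho`` behaves, in the lumped
(zero-dimensional) limit, like a series viscous resistance with an
inertance and a wall compliance:

    R = 8 nu l / (pi r^4)        Poiseuille resistance, J.s.m-6
    I = rho l / (pi r^2)         blood column inertance, J.s2.m-6
    C = 2 pi r^3 l / (E h)       wall compliance, m6.J-1

with Young's modulus ``E`` and wall thickness ``h`` following the
empirical two-exponential fit h = r (a e^{b r} + c e^{d r}).

Three templates cover a whole arterial tree:

* ``initial``      — embeds the cardiac-output flow source (Sf),
* ``intermediate`` — generic (possibly branching) segment; exposes an
  inlet potential port ``u_x`` and ``n_branch_ports`` auxiliary flow
  ports ``v_x`` on its outlet 0-junction,
* ``terminal``     — ends on a terminal bed resistance against a venous
  pressure source (Se).

The default wiring is: inlet 1-junction (R and I attached, ``u_x`` port
on non-initial kinds) -> outlet 0-junction (flow ports) -> wall branch,
a 1-junction carrying the compliance and an optional series viscoelastic
resistor.  An optional ``compliance_split="half"`` mode instead places
C/2 (+R_A, +R_B) wall branches at both segment ends; the default single
full-C branch avoids double-counting compliance where segments join.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import Bond, Component, Junction, Module, Port, build_module

SEGMENT_KINDS = ("initial", "intermediate", "terminal")

#: default maximum number of daughter branches a segment can feed
DEFAULT_BRANCH_PORTS = 4


@dataclass(frozen=True)
class VesselProperties:
    """Global vascular constants (blood and wall properties).

    Defaults are the standard values for human systemic arteries:
    nu = 0.004 J.s.m-3, rho = 1050 J.s2.m-5, E = 0.4e6 J.m-3 and the
    wall-thickness fit coefficients a, b, c, d (a, c dimensionless;
    b, d in m-1).
    """

    nu: float = 0.004
    rho: float = 1050.0
    E: float = 0.4e6
    a: float = 0.2802
    b: float = -505.3
    c: float = 0.1324
    d: float = -11.14

    def __post_init__(self):
        for name in ("nu", "rho", "E"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class VesselGeometry:
    """Per-segment geometry: length and (inner) radius, metres."""

    l: float
    r: float

    def __post_init__(self):
        if self.l <= 0 or self.r <= 0:
            raise ValueError("length and radius must be positive")


@dataclass(frozen=True)
class SegmentParams:
    R: float  # J.s.m-6
    I: float  # J.s2.m-6
    C: float  # m6.J-1
    h: float  # m


def wall_thickness(r: float, props: VesselProperties = VesselProperties()) -> float:
    """Wall thickness h = r (a e^{b r} + c e^{d r}); h(0) = 0."""
    if r < 0:
        raise ValueError("radius must be non-negative")
    return r * (props.a * math.exp(props.b * r) + props.c * math.exp(props.d * r))


def segment_params(geom: VesselGeometry,
                   props: VesselProperties = VesselProperties()) -> SegmentParams:
    """Lumped R, I, C (and wall thickness) of one vessel segment."""
    l, r = geom.l, geom.r
    h = wall_thickness(r, props)
    return SegmentParams(
        R=8.0 * props.nu * l / (math.pi * r ** 4),
        I=props.rho * l / (math.pi * r ** 2),
        C=2.0 * math.pi * r ** 3 * l / (props.E * h),
        h=h,
    )


def _wall_branch(name, zero_jid, tag, C_value, R_visc, comps, juncs, bonds):
    """Attach a compliance wall branch (1-junction with C and optional
    series viscoelastic R) to the given 0-junction."""
    jw = Junction(f"{name}.j_wall{tag}", "one")
    juncs.append(jw)
    bonds.append(Bond(f"{name}.b_wall{tag}", zero_jid, jw.id))
    cw = Component(f"{name}.c_wall{tag}", "C", C_value)
    comps.append(cw)
    bonds.append(Bond(f"{name}.b_c{tag}", jw.id, cw.id))
    if R_visc:
        rv = Component(f"{name}.r_visc{tag}", "R", R_visc)
        comps.append(rv)
        bonds.append(Bond(f"{name}.b_rv{tag}", jw.id, rv.id))
    return cw


def make_segment(kind: str, name: str, geom: VesselGeometry,
                 props: VesselProperties = VesselProperties(), *,
                 n_branch_ports: int = DEFAULT_BRANCH_PORTS,
                 compliance_split: str = "full",
                 R_A: float = 0.0, R_B: float = 0.0,
                 terminal_resistance: float = 1e8,
                 venous_pressure: float = 0.0,
                 inflow: "float | str" = "cardiac_output") -> Module:
    """Instantiate one vessel segment template as a validated Module.

    Parameters
    ----------
    kind
        ``initial`` (embeds an Sf flow source), ``intermediate`` or
        ``terminal`` (embeds the terminal bed resistance and an Se
        venous pressure source).
    n_branch_ports
        Auxiliary ``v_x`` flow ports exposed on the outlet 0-junction of
        initial/intermediate segments (a priori maximum branching).
    compliance_split
        ``"full"`` (default): the whole C in one wall branch at the
        outlet.  ``"half"``: C/2 branches at both inlet and outlet, each
        optionally with its viscoelastic resistor R_A / R_B.
    R_A, R_B
        Viscoelastic wall resistances (0 disables; no published value).
    terminal_resistance, venous_pressure
        Terminal bed R and Se value for ``terminal`` segments; the
        venous pressure defaults to 0 (gauge).
    inflow
        For ``initial`` segments: Sf value, either a constant flow in
        m3/s or the name of a time function supplied at simulation time.
    """
    if kind not in SEGMENT_KINDS:
        raise ValueError(f"unknown segment kind {kind!r}")
    if kind != "terminal" and n_branch_ports < 1:
        raise ValueError("n_branch_ports must be >= 1 for branching kinds")
    if compliance_split not in ("full", "half"):
        raise ValueError(f"unknown compliance_split {compliance_split!r}")

    p = segment_params(geom, props)
    comps, juncs, bonds, ports = [], [], [], []

    j_in = Junction(f"{name}.j_in", "one")
    juncs.append(j_in)
    comps.append(Component(f"{name}.R", "R", p.R))
    bonds.append(Bond(f"{name}.b_R", j_in.id, f"{name}.R"))
    comps.append(Component(f"{name}.I", "I", p.I))
    bonds.append(Bond(f"{name}.b_I", j_in.id, f"{name}.I"))

    j_out = Junction(f"{name}.j_out", "zero")
    juncs.append(j_out)
    bonds.append(Bond(f"{name}.b_axis", j_in.id, j_out.id))

    if kind == "initial":
        # cardiac output feeds the inlet through a leading 0-junction
        j0 = Junction(f"{name}.j_src", "zero")
        juncs.append(j0)
        comps.append(Component(f"{name}.Sf", "Sf", inflow))
        bonds.append(Bond(f"{name}.b_Sf", f"{name}.Sf", j0.id))
        bonds.append(Bond(f"{name}.b_in", j0.id, j_in.id))
        # a flow source in series with the inertance through a bare
        # 0-junction double-determines the flow (index-2 constraint), so
        # the initial segment always uses the two-ended wall arrangement:
        # C/2 at the source junction (aortic-root compliance) and C/2 at
        # the outlet, regardless of compliance_split
        split = True
    else:
        ports.append(Port(f"{name}.ux", j_in.id, "potential"))
        split = compliance_split == "half"

    if not split:
        _wall_branch(name, j_out.id, "", p.C, R_A or R_B, comps, juncs, bonds)
    else:
        if kind == "initial":
            inlet_zero = f"{name}.j_src"
        else:
            j0i = Junction(f"{name}.j_in0", "zero")
            juncs.append(j0i)
            bonds.append(Bond(f"{name}.b_in0", j0i.id, j_in.id))
            inlet_zero = j0i.id
        _wall_branch(name, inlet_zero, "_A", p.C / 2.0, R_A, comps, juncs, bonds)
        _wall_branch(name, j_out.id, "_B", p.C / 2.0, R_B, comps, juncs, bonds)

    if kind == "terminal":
        j_term = Junction(f"{name}.j_term", "one")
        juncs.append(j_term)
        bonds.append(Bond(f"{name}.b_term", j_out.id, j_term.id))
        comps.append(Component(f"{name}.R_term", "R", terminal_resistance))
        bonds.append(Bond(f"{name}.b_Rt", j_term.id, f"{name}.R_term"))
        comps.append(Component(f"{name}.Se", "Se", venous_pressure))
        bonds.append(Bond(f"{name}.b_Se", j_term.id, f"{name}.Se"))
    else:
        for k in range(1, n_branch_ports + 1):
            ports.append(Port(f"{name}.vx{k}", j_out.id, "flow"))

    return build_module(name, comps, juncs, bonds, ports)
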