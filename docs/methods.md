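# Methods

## Scope and model class

hemobond builds zero-dimensional (lumped-parameter) models of arterial
networks as bond graphs: directed power bonds carrying a potential
u (pressure, J·m⁻³ ≡ Pa) and a flow v (m³·s⁻¹), one-port elements
R / C / I / Se / Sf, and 0/1-junctions enforcing the conservation laws.
Pressure–flow dynamics within a segment are linear; there are no
nonlinear pressure–area laws, no tapering within a segment, no 1-D wave
propagation, and no closed-loop heart or reflex control.

## Segment parameters

For a segment of length l and radius r:

* R = 8νl/(πr⁴), I = ρl/(πr²), C = 2πr³l/(Eh), h = r(a·e^{br} + c·e^{dr}).
* Defaults (human systemic arteries): ν = 0.004 J·s·m⁻³, ρ = 1050 J·s²·m⁻⁵,
  E = 0.4×10⁶ J·m⁻³, a = 0.2802, b = −505.3 m⁻¹, c = 0.1324, d = −11.14 m⁻¹.
  All are overridable through a properties file; l and r are per segment.
* R and I are strictly decreasing in r, C strictly increasing, over the
  physiological range r ∈ (0, 0.02] m (verified numerically in the tests).

## Template topology

Three templates cover a tree: **initial** (embeds the cardiac-output flow
source Sf), **intermediate**, **terminal** (embeds a terminal bed
resistance in series with a venous pressure source Se).  The default
wiring is: inlet 1-junction carrying R and I (and, on non-initial kinds,
the auxiliary potential port u_x) → outlet 0-junction exposing
`n_branch_ports` auxiliary flow ports (default 4, the a-priori maximum
branching) → a wall branch: a 1-junction with the compliance and an
optional series viscoelastic resistor.

Design choices made where the wiring was genuinely open:

* **Compliance placement.** By default the full C sits in a single wall
  branch at the segment outlet, which avoids double-counting compliance
  where segments join.  An optional `compliance_split="half"` mode places
  C/2 (+R_A, +R_B) branches at both segment ends.
* **Initial segments always use the two-ended (C/2 + C/2) arrangement.**
  A flow source in series with an inertance through a bare 0-junction
  double-determines the flow (an index-2 constraint with no ODE form);
  inlet compliance — physically, aortic-root compliance — restores
  well-posedness.  Consequence: an initial segment contributes 2 C states,
  so a 5-segment network has 11 states (6 C + 5 I), and in general the
  state count is always #C + #I components.
* **Viscoelastic wall resistances R_A/R_B** have no published value here;
  they default to 0 (the wall branch degenerates to a pure compliance) and
  are settable per segment.  Which of the two sits inlet- versus
  outlet-side is not determinable from first principles; R_A is assigned
  to the inlet branch.
* **Terminal boundary.** Venous pressure Se defaults to 0 (gauge); the
  terminal bed resistance defaults to 10⁸ J·s·m⁻⁶ (order of a single
  peripheral bed); both are required, documented configuration in any
  quantitative use.
* Bonds directly between two junctions are permitted (junction chains
  need them).

## Sign conventions

Positive power flows tail → head along a bond.  A bond oriented into a
junction enters that junction's sum equation with +, out with −.  Flow
ports enter the 0-junction flow sum with −(bound value), potential ports
enter the 1-junction potential sum with +(bound value); unbound ports are
exactly 0.  With this convention a coupled pair reproduces the shared
wall-junction relation v* = −v_up − v_down, and binding a port is
algebraically identical to adding a physical bond.

## Semantic composition

Annotations are triples (variable, property, entity) with the closed
property vocabulary {potential, flow, time, parameter:<name>} and opaque
entity strings; no ontology reasoning is attempted (curated terms are
assumed, with a human able to veto proposals).  Exact proposals pair
identical (property, entity) keys where exactly one side is a port or
source placeholder; time is always unifiable; property-only matches are
reported as advisory "partial" proposals.  One accepted flow mapping
binds both directions (flow port downstream-ward, potential port
upstream-ward) — accepting only half of an energy coupling is not
offered, since it would break conservation at the seam.  When several
ports share an entity term the automatic resolver raises an ambiguity
error rather than guessing.  Plans fold depth-first left-to-right with
n−1 binary merges for n leaves; because element ids are namespaced once
at construction (`segment.element`) and never re-prefixed, merge order
changes nothing but the fold's intermediate names.

## ODE assembly and numerics

All constitutive laws are linear and parameters are bound numerically, so
the junction equalities, port substitutions and component laws form a
square sparse linear system in the bond/junction co-variables with a
right-hand side linear in the states (q per C, v per I) and the Sf time
functions.  It is solved once by sparse LU followed by two steps of
iterative refinement; refinement makes the solution residual-limited, so
structurally equivalent builds (port-coupled vs directly bonded) yield
numerically identical coefficient matrices to ~10⁻¹³ relative.  A
structurally singular subsystem (e.g. a compliance in parallel with an
ideal pressure source, or any index > 1 arrangement) raises an assembly
error rather than being regularised.  The inertance state is the flow
itself (dv/dt = u/I) rather than generalized momentum — equivalent for
linear I and directly comparable to reported flow traces.  The
compliance law is u = q/C with dq/dt = v throughout, for any compliance
value including the C/2 branches.  Variable ordering is lexicographic
everywhere, so generated systems are reproducible bit-for-bit.

Unbound ports are warnings, not errors: an isolated module with its
ports at zero is a legitimate, runnable model.

## Simulation

Integration uses SciPy's LSODA by default (the wall time constants
R·C ~ 10⁻⁴ s sit far below the 1 s beat, making the systems stiff),
from all-zero initial states, with traces stored on a uniform 1 ms grid.
Zero initial conditions are a convention, not a claim — steady-cycle
analysis (`last_cycle`, e.g. seconds 9–10 of a 10 s run) removes the
start-up transient, and the toy network's cycle-to-cycle convergence at
t = 10 s is ~5×10⁻⁷ relative.

The cardiac inflow is a periodic two-term Gaussian
f(t) = Σᵢ aᵢ·exp(−((t mod T − bᵢ)/cᵢ)²).  The shipped default
(a₁ = 4.2×10⁻⁴ m³/s at b₁ = 0.15 s, c₁ = 0.08 s; a₂ = 1.0×10⁻⁴ m³/s at
b₂ = 0.30 s, c₂ = 0.08 s; T = 1 s) is a synthetic single-peak ejection
wave with ~4.5 L/min mean output at 60 bpm.  **It is not a fit to any
published waveform**; quantitative studies must supply their own
parameter file.  The beat period default T = 1 s is likewise a
convention.

## Validation machinery

* **Power audit**: the signed per-junction power sum Σᵢ uᵢvᵢ (including
  bound-port contributions) is re-evaluated on the stored trajectory;
  conservation holds to solver tolerance (observed ~10⁻¹⁶ relative,
  audited against ≤10⁻⁸).
* **NRMSE**: 100·RMSE/(y_max − y_min) with the range taken from the
  reference series; a constant reference is an error, not 0%.  Grids are
  aligned by linear interpolation onto the coarser grid over the
  overlapping span (a choice — the comparisons here are same-environment
  runs, where it is exact).

## Synthetic fixtures — what they do and do not establish

The toy tree (5 segments, fixed geometry) and the seeded random trees
(parent/child radius ratio 0.8, length = 10r, all leaves terminal)
emulate the *structure* of an arterial tree: branching under a port
capacity limit, radii decreasing rootward→leafward, stiffness ratios in
a plausible range.  They do not reproduce measured anatomy, peripheral
impedance tuning, or a published flow waveform.  A green test therefore
establishes the correctness of the machinery — template construction,
composition-equals-monolithic equivalence, energy conservation, solver
convergence, clone symmetry — not agreement with any measured or
published pressure/flow trace.  The shipped seven-subdivision whole-body
plan (head and neck, heart, trunk, four limbs with the right limbs
cloned from the left) is likewise a synthetic stand-in per subdivision;
only its subdivision structure mirrors the real open-loop arterial
hierarchy, whose 86-segment geometry is optional external data.

## Known limitations

* Linear, index-≤1 systems only; no DAE regularisation, no events,
  no stochastic terms.
* No transformer/gyrator elements (not needed for vessel networks).
* Entity terms are opaque strings; no ontology resolution or inference
  of annotations from variable names.
* The CLI covers the file-based workflow; plotting is left to the user
  (traces export as tidy CSV).
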