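# hemobond

Energy-conserving, modular lumped-parameter models of arterial networks,
built as **bond graphs** and composed automatically through **semantic
annotations**.

## Who this is for

Cardiovascular and systems-biology modellers who want to assemble large
zero-dimensional (lumped) hemodynamic networks from small, reusable,
independently testable modules — without hand-editing the merged equations,
and with a machine-checkable guarantee that every coupling conserves energy.

## The model

A vessel segment of length *l* and radius *r* behaves as an RLC compartment:

    R = 8 ν l / (π r⁴)        viscous (Poiseuille) resistance   [J·s·m⁻⁶]
    I = ρ l / (π r²)          blood column inertance            [J·s²·m⁻⁶]
    C = 2 π r³ l / (E h)      wall compliance                   [m⁶·J⁻¹]

with blood viscosity ν, density ρ, Young's modulus E, and wall thickness
h = r(a·e^{br} + c·e^{dr}).  Bonds carry pressure u (J·m⁻³) and volumetric
flow v (m³·s⁻¹); their product is power.  At a `0 : u` junction all bond
potentials are equal and signed flows sum to zero; at a `1 : v` junction
flows are equal and signed potentials sum to zero — so Σᵢ uᵢ·vᵢ = 0 at every
junction, and the whole network is thermodynamically consistent by
construction.

Three segment **templates** (initial with a cardiac-output flow source,
intermediate, terminal with a bed resistance against venous pressure)
suffice for a whole arterial tree.  Each template exposes auxiliary port
variables — flow ports `v_x` on its outlet 0-junction, a potential port
`u_x` on its inlet 1-junction — that default to zero.  **Merging** two
modules binds one module's flow port to the other's inlet flow and,
reciprocally, the inlet's potential port to the upstream junction pressure:
exactly the equations that adding a physical bond would produce, but
without editing either module.  Matches are proposed automatically from
annotation triples (variable, physical property, anatomical entity).
Hierarchical plans lump sub-networks (n leaves → n−1 binary merges), and
symmetric structures (the contralateral limb) are reused by cloning.

The composed network is assembled into an explicit linear ODE system
(states: excess volume q per compliance, flow v per inertance), integrated
with a stiff-capable adaptive solver, and validated by (a) a per-junction
**power audit** along the trajectory and (b) **NRMSE** trace comparison,
`100·RMSE/(y_max − y_min)` against the reference run.

## Worked example

```python
import hemobond as hb

# a fixed 5-segment tree: 1 initial, 2 intermediates, 2 terminals
modules, plan, geometry = hb.toy_tree()

network, n_merges = hb.lump(plan)          # 4 merges for 5 modules
system = hb.assemble_ode(network)          # 11 states (6 C + 5 I)
result = hb.run(system, {"cardiac_output": hb.DEFAULT_BEAT}, t_end=10.0)

beat = hb.last_cycle(result, T=1.0)        # steady cycle, seconds 9-10
u = beat["root.j_out.u"]                   # aortic-root pressure trace
print(u.max() / 133.322)                   # -> 95.7  (peak, mmHg)

audit = hb.power_audit(system, result)
print(audit.max_relative)                  # -> 3.7e-16 (energy conserved)

mono = hb.assemble_ode(hb.monolithic_from_geometry(geometry))
ref = hb.run(mono, {"cardiac_output": hb.DEFAULT_BEAT}, t_end=10.0)
cmp = hb.compare_runs(
    hb.SimulationResult(result.t, {k: result[k] for k in system.states}),
    hb.SimulationResult(ref.t, {k: ref[k] for k in mono.states}))
print(cmp.max_nrmse)                       # -> 0.0  (% — composed == monolithic)
```

The composed (port-bound) network reproduces the monolithically built one
exactly: peak root pressure 12 761 J·m⁻³ (95.7 mmHg), peak mid-tree flow
3.7×10⁻⁴ m³·s⁻¹, worst per-junction power residual ~4×10⁻¹⁶ relative, and
0% NRMSE between the two builds.  (The toy tree has no peripheral tone
tuning, so its diastolic pressure is unphysiologically low; it is a
structural fixture, not a patient model.)

The same workflow is scriptable from the shell:

```bash
hemobond build geometry.tsv --out-dir mods --plan-out plan.json
hemobond lump plan.json --out network.json
hemobond simulate --model network.json --t-end 10 --last-cycle 1 --out traces.csv
hemobond audit --model network.json --traces traces.csv
hemobond compare traces.csv reference.csv
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch: it builds
the toy network and seeded random trees, composes them hierarchically,
simulates beat-driven runs, audits per-junction energy conservation,
verifies composed-vs-monolithic agreement by NRMSE, and exercises the
seven-subdivision whole-body plan with cloned limbs.  It exits non-zero if
any internal consistency check fails and writes its JSON results file to
`--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the modelling assumptions, default parameters and
known limitations.
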