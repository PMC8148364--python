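"""Trace comparison (NRMSE), module/plan/waveform serialization, CSV export.

Agreement between two simulations is summarised per variable by the
normalised root-mean-square error, in percent:

    NRMSE = 100 * sqrt( sum_i (yhat_i - y_i)^2 / n ) / (y_max - y_min)

where ``y`` is the *reference* series and the normalisation range
``y_max - y_min`` is taken from the reference.  A constant reference
has zero range and the comparison is undefined (an error, not 0 or
infinity).

Serialization uses a plain JSON module document (see
``module.schema.json`` next to this file): top-level keys ``name``,
``components``, ``junctions``, ``bonds``, ``ports``, ``annotations``;
unit strings are preserved byte-for-byte.  Documents are structurally
validated on both write and read; violations report a JSON-pointer-like
location (e.g. ``/components/2/kind``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .compose import CompositionPlan
from .core import (AnnotationTriple, Bond, BondGraphError, Component,
                   Junction, Module, Port, validate_module)
from .simulate import BeatWaveform, SimulationResult


class SchemaError(BondGraphError):
    """A module document violates the exchange format."""

    def __init__(self, pointer, message):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


# ---------------------------------------------------------------------------
# NRMSE
# ---------------------------------------------------------------------------

def nrmse(test, reference) -> float:
    """NRMSE of ``test`` against ``reference``, in percent of the
    reference's max-min range."""
    yhat = np.asarray(test, dtype=float)
    y = np.asarray(reference, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError(
            f"length mismatch: test {yhat.shape} vs reference {y.shape}")
    if y.size < 2:
        raise ValueError("need at least two points")
    rng = float(np.max(y) - np.min(y))
    if rng == 0.0:
        raise ValueError("zero range: constant reference series")
    rmse = math.sqrt(float(np.mean((yhat - y) ** 2)))
    return 100.0 * rmse / rng


@dataclass
class TraceComparison:
    """Per-variable NRMSE between two runs on a common grid."""

    nrmse_percent: dict
    n: int
    ranges: dict   # reference y_max - y_min per variable

    @property
    def max_nrmse(self) -> float:
        return max(self.nrmse_percent.values()) if self.nrmse_percent else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": list(self.nrmse_percent),
            "nrmse_percent": list(self.nrmse_percent.values()),
            "reference_range": [self.ranges[k] for k in self.nrmse_percent],
        })


def compare_runs(a: SimulationResult, b: SimulationResult,
                 variables=None) -> TraceComparison:
    """NRMSE of run ``a`` against reference run ``b`` per variable.

    Grids are aligned by linear interpolation onto the coarser of the
    two over their overlapping span.
    """
    if variables is None:
        variables = sorted(set(a.traces) & set(b.traces))
    t0 = max(a.t[0], b.t[0])
    t1 = min(a.t[-1], b.t[-1])
    if t1 <= t0:
        raise ValueError("runs do not overlap in time")
    coarse = a.t if a.t.size <= b.t.size else b.t
    grid = coarse[(coarse >= t0 - 1e-15) & (coarse <= t1 + 1e-15)]

    out, ranges = {}, {}
    for v in variables:
        if v not in a.traces or v not in b.traces:
            raise KeyError(f"variable {v!r} absent from one of the runs")
        ya = np.interp(grid, a.t, np.asarray(a.traces[v]))
        yb = np.interp(grid, b.t, np.asarray(b.traces[v]))
        out[v] = nrmse(ya, yb)
        ranges[v] = float(np.max(yb) - np.min(yb))
    return TraceComparison(out, int(grid.size), ranges)


# ---------------------------------------------------------------------------
# module documents
# ---------------------------------------------------------------------------

_COMPONENT_KEYS = {"id", "kind", "param", "units", "state_id"}


def _expect(cond, pointer, message):
    if not cond:
        raise SchemaError(pointer, message)


def module_to_doc(m: Module) -> dict:
    return {
        "name": m.name,
        "components": [
            {"id": c.id, "kind": c.kind, "param": c.param, "units": c.units,
             **({"state_id": c.state_id} if c.state_id else {})}
            for c in m.components],
        "junctions": [{"id": j.id, "kind": j.kind} for j in m.junctions],
        "bonds": [{"id": b.id, "tail": b.tail, "head": b.head}
                  for b in m.bonds],
        "ports": [{"id": p.id, "junction": p.junction, "kind": p.kind,
                   "binding": p.binding} for p in m.ports],
        "annotations": [
            {"variable": t.variable, "property_term": t.property_term,
             "entity_term": t.entity_term}
            for t in m.annotations.values()],
    }


def doc_to_module(doc: dict) -> Module:
    _expect(isinstance(doc, dict), "/", "module document must be an object")
    for key in ("name", "components", "junctions", "bonds", "ports",
                "annotations"):
        _expect(key in doc, f"/{key}", "missing required key")
    _expect(isinstance(doc["name"], str), "/name", "must be a string")

    comps = []
    for i, d in enumerate(doc["components"]):
        ptr = f"/components/{i}"
        for k in ("id", "kind", "param"):
            _expect(k in d, f"{ptr}/{k}", "missing required key")
        _expect(isinstance(d["id"], str), f"{ptr}/id", "must be a string")
        _expect(d["kind"] in ("R", "C", "I", "Se", "Sf"), f"{ptr}/kind",
                f"unknown component kind {d['kind']!r}")
        _expect(isinstance(d["param"], (int, float, str)), f"{ptr}/param",
                "must be a number or a time-function name")
        comps.append(Component(d["id"], d["kind"], d["param"],
                               d.get("units", ""), d.get("state_id")))
    juncs = []
    for i, d in enumerate(doc["junctions"]):
        ptr = f"/junctions/{i}"
        _expect(d.get("kind") in ("zero", "one"), f"{ptr}/kind",
                f"unknown junction kind {d.get('kind')!r}")
        _expect(isinstance(d.get("id"), str), f"{ptr}/id", "must be a string")
        juncs.append(Junction(d["id"], d["kind"]))
    bonds = []
    for i, d in enumerate(doc["bonds"]):
        ptr = f"/bonds/{i}"
        for k in ("id", "tail", "head"):
            _expect(isinstance(d.get(k), str), f"{ptr}/{k}",
                    "must be a string")
        bonds.append(Bond(d["id"], d["tail"], d["head"]))
    ports = []
    for i, d in enumerate(doc["ports"]):
        ptr = f"/ports/{i}"
        _expect(d.get("kind") in ("flow", "potential"), f"{ptr}/kind",
                f"unknown port kind {d.get('kind')!r}")
        _expect(isinstance(d.get("id"), str), f"{ptr}/id", "must be a string")
        _expect(isinstance(d.get("junction"), str), f"{ptr}/junction",
                "must be a string")
        b = d.get("binding")
        _expect(b is None or isinstance(b, str), f"{ptr}/binding",
                "must be null or a variable name")
        ports.append(Port(d["id"], d["junction"], d["kind"], b))
    annotations = {}
    for i, d in enumerate(doc["annotations"]):
        ptr = f"/annotations/{i}"
        for k in ("variable", "property_term", "entity_term"):
            _expect(isinstance(d.get(k), str), f"{ptr}/{k}",
                    "must be a string")
        annotations[d["variable"]] = AnnotationTriple(
            d["variable"], d["property_term"], d["entity_term"])

    m = Module(doc["name"], comps, juncs, bonds, ports, annotations)
    bad = validate_module(m)
    if bad:
        raise SchemaError("/", "invalid module: " + "; ".join(bad))
    return m


def save_module(m: Module, path) -> None:
    bad = validate_module(m)
    if bad:
        raise SchemaError("/", "refusing to write invalid module: "
                          + "; ".join(bad))
    Path(path).write_text(json.dumps(module_to_doc(m), indent=1) + "\n")


def load_module(path) -> Module:
    return doc_to_module(json.loads(Path(path).read_text()))


def roundtrip(m: Module) -> Module:
    """Serialize then parse; the result is deep-equal to the input."""
    return doc_to_module(json.loads(json.dumps(module_to_doc(m))))


# ---------------------------------------------------------------------------
# plans and waveforms
# ---------------------------------------------------------------------------

def plan_to_doc(plan: CompositionPlan, module_dir: str = "") -> dict:
    """Leaf entries reference ``<module_dir>/<name>.json`` relative to
    wherever the plan file will live."""
    if plan.is_leaf:
        fname = f"{plan.module.name}.json"
        return {"module": f"{module_dir}/{fname}" if module_dir else fname}
    return {"name": plan.name,
            "children": [plan_to_doc(c, module_dir) for c in plan.children]}


def save_plan(plan: CompositionPlan, path, module_dir: str = "") -> None:
    Path(path).write_text(
        json.dumps(plan_to_doc(plan, module_dir), indent=1) + "\n")


def load_plan(path, module_loader=load_module) -> CompositionPlan:
    """Read a plan tree; leaf ``module`` paths resolve relative to the
    plan file and are loaded with ``module_loader``."""
    path = Path(path)
    doc = json.loads(path.read_text())

    def walk(d, ptr):
        if "module" in d:
            return CompositionPlan.leaf(module_loader(path.parent / d["module"]))
        _expect("children" in d and isinstance(d["children"], list),
                f"{ptr}/children", "plan node needs children or module")
        return CompositionPlan.node(
            d.get("name", "lumped"),
            [walk(c, f"{ptr}/children/{i}")
             for i, c in enumerate(d["children"])])

    return walk(doc, "")


def save_waveform(w: BeatWaveform, path) -> None:
    doc = {"terms": [{"a": a, "b": b, "c": c} for (a, b, c) in w.terms],
           "period": w.period}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_waveform(path) -> BeatWaveform:
    doc = json.loads(Path(path).read_text())
    terms = tuple((t["a"], t["b"], t["c"]) for t in doc["terms"])
    return BeatWaveform(terms=terms, period=doc.get("period", 1.0))


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def result_to_frame(res: SimulationResult, variables=None) -> pd.DataFrame:
    cols = {"t": res.t}
    for k in (variables if variables is not None else sorted(res.traces)):
        cols[k] = np.asarray(res.traces[k])
    return pd.DataFrame(cols)


def save_traces(res: SimulationResult, path, variables=None) -> None:
    result_to_frame(res, variables).to_csv(path, index=False)


def load_traces(path) -> SimulationResult:
    df = pd.read_csv(path)
    t = df.pop("t").to_numpy()
    return SimulationResult(t=t, traces={k: df[k].to_numpy() for k in df})
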