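"""Scenario execution: dose events, single/multiple dosing, parameter
scans, and study emulation.

A :class:`Scenario` bundles physiology, drug and PD parameters with a
dosing regimen and an output grid. :func:`simulate` integrates the ODE
core piecewise between dose events (stiff-capable adaptive solver,
restarted at each event so boluses are applied exactly), then derives
reported quantities: plasma concentrations (ng/mL), cumulative urinary
and fecal amounts (mg), the renal glucose threshold (mM), and cumulative
urinary glucose excretion (g). Simulations are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.integrate import solve_ivp

from . import nca as _nca
from .pbpk import (IX, MW_GLUCOSE, N_STATES, DrugParameters, build_rhs)
from .pharmacodynamics import PDParameters, cumulative_uge, rtg
from .physiology import PhysiologyState

__all__ = [
    "DoseEvent", "Scenario", "TimeCourse", "ScanResult",
    "simulate", "parameter_scan", "run_study",
    "QUANTITY_UNITS",
]

#: Reported quantities and their units (fixed dialect, see README).
QUANTITY_UNITS = {
    "dap_plasma": "ng/ml",
    "d3g_plasma": "ng/ml",
    "dap_urine": "mg",
    "d3g_urine": "mg",
    "dap_feces": "mg",
    "rtg": "mM",
    "uge": "g",
}

DEFAULT_GRID_DT_H = 0.1


@dataclass(frozen=True)
class DoseEvent:
    time: float          # h
    route: str           # "oral" | "iv"
    amount: float        # mg

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be non-negative, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be non-negative, got {self.amount}")
        if self.route not in ("oral", "iv"):
            raise ValueError(f"unknown route {self.route!r}; expected 'oral' or 'iv'")


@dataclass(frozen=True)
class Scenario:
    physiology: PhysiologyState
    drug: DrugParameters
    pd: PDParameters
    doses: tuple[DoseEvent, ...] = ()
    t_end: float = 48.0                       # h
    output_grid: tuple[float, ...] | None = None
    label: str = "scenario"

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(self.doses))
        times = [d.time for d in self.doses]
        if times != sorted(times):
            raise ValueError("dose events must be sorted by time")
        if times and self.t_end < times[-1]:
            raise ValueError("t_end must not precede the last dose event")
        if self.t_end <= 0:
            raise ValueError(f"t_end must be positive, got {self.t_end}")
        if self.output_grid is not None:
            g = np.asarray(self.output_grid, dtype=float)
            if g.ndim != 1 or len(g) < 2 or np.any(np.diff(g) <= 0):
                raise ValueError("output grid must be strictly increasing with >= 2 points")
            object.__setattr__(self, "output_grid", tuple(float(x) for x in g))

    def grid(self) -> np.ndarray:
        if self.output_grid is not None:
            return np.asarray(self.output_grid, dtype=float)
        n = int(round(self.t_end / DEFAULT_GRID_DT_H))
        return np.linspace(0.0, n * DEFAULT_GRID_DT_H, n + 1)


class TimeCourse:
    """Time grid with named, unit-carrying series.

    Cumulative series (urine, feces, UGE) are non-decreasing. The raw
    state matrix (µmol) and cumulative administered dose are retained on
    simulator output for mass-balance checks; they are not round-tripped
    through CSV.
    """

    def __init__(self, time, quantities, units=None, label="timecourse",
                 states=None, dose_umol=None):
        self.time = np.asarray(time, dtype=float)
        if self.time.ndim != 1 or (len(self.time) > 1 and np.any(np.diff(self.time) <= 0)):
            raise ValueError("time grid must be one-dimensional and strictly increasing")
        self.quantities = {k: np.asarray(v, dtype=float) for k, v in quantities.items()}
        for k, v in self.quantities.items():
            if v.shape != self.time.shape:
                raise ValueError(f"series {k!r} length does not match the time grid")
        self.units = dict(units) if units is not None else {
            k: QUANTITY_UNITS.get(k, "") for k in self.quantities}
        self.label = label
        self.states = states
        self.dose_umol = dose_umol

    def __getitem__(self, key: str) -> np.ndarray:
        return self.quantities[key]

    def __contains__(self, key: str) -> bool:
        return key in self.quantities

    def to_frame(self):
        """Tidy DataFrame with columns time_h, quantity, value, unit."""
        import pandas as pd
        rows = []
        for name, values in self.quantities.items():
            unit = self.units.get(name, "")
            for t, v in zip(self.time, values):
                rows.append((t, name, v, unit))
        return pd.DataFrame(rows, columns=["time_h", "quantity", "value", "unit"])


def _dose_umol(event: DoseEvent, drug: DrugParameters) -> float:
    return 1000.0 * event.amount / drug.MW_DAP  # mg -> µmol


def _apply_event(y: np.ndarray, event: DoseEvent, drug: DrugParameters) -> None:
    amount = _dose_umol(event, drug)
    if event.route == "oral":
        y[IX["lumen_dap"]] += amount * drug.F_gut
        y[IX["feces_transit_dap"]] += amount * (1.0 - drug.F_gut)
    else:
        y[IX["blood_dap"]] += amount


def simulate(scenario: Scenario, rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA") -> TimeCourse:
    """Integrate a scenario and return its TimeCourse.

    Integration is restarted at every dose event; grid points that
    coincide with an event report the post-dose state.
    """
    grid = scenario.grid()
    phys, drug = scenario.physiology, scenario.drug
    rhs = build_rhs(phys, drug)

    event_times = sorted({d.time for d in scenario.doses})
    boundaries = sorted({0.0, *event_times, float(grid[-1])})
    if boundaries[-1] < grid[-1]:
        boundaries.append(float(grid[-1]))

    y = np.zeros(N_STATES)
    out = np.empty((len(grid), N_STATES))
    filled = np.zeros(len(grid), dtype=bool)

    for i, t0 in enumerate(boundaries):
        for d in scenario.doses:
            if d.time == t0:
                _apply_event(y, d, drug)
        if t0 == boundaries[-1]:
            at_end = np.isclose(grid, t0) & ~filled
            out[at_end] = y
            filled |= at_end
            break
        t1 = boundaries[i + 1]
        sel = (grid >= t0) & (grid < t1) if t1 < boundaries[-1] else (grid >= t0) & (grid <= t1)
        t_eval = np.unique(np.concatenate([grid[sel], [t1]]))
        if np.any(y != 0.0):
            sol = solve_ivp(rhs, (t0, t1), y, method=method, t_eval=t_eval,
                            rtol=rtol, atol=atol)
            if not sol.success:
                raise RuntimeError(
                    f"ODE integration failed for scenario {scenario.label!r} "
                    f"on [{t0}, {t1}] h: {sol.message}")
            values = sol.y.T
        else:  # empty system stays empty; skip the solver
            values = np.zeros((len(t_eval), N_STATES))
        for j, te in enumerate(t_eval):
            hits = np.isclose(grid, te) & sel & ~filled
            out[hits] = values[j]
            filled[hits] = True
        y = values[-1].copy()

    if not filled.all():  # pragma: no cover - grid bookkeeping guard
        raise RuntimeError("internal error: output grid not fully covered")

    # Non-negativity: clip solver noise, reject genuine negativity.
    total_dose = sum(_dose_umol(d, drug) for d in scenario.doses)
    neg_tol = 1e-6 * max(total_dose, 1.0)
    if out.min() < -neg_tol:
        raise RuntimeError(
            f"negative state amounts beyond tolerance in scenario "
            f"{scenario.label!r} (min {out.min():.3e} µmol)")
    out = np.clip(out, 0.0, None)

    cum_dose = np.array([
        sum(_dose_umol(d, drug) for d in scenario.doses if d.time <= t + 1e-12)
        for t in grid])

    V_bl = phys.V_bl
    dap_plasma = out[:, IX["blood_dap"]] / V_bl * drug.MW_DAP    # µM * g/mol = ng/mL
    d3g_plasma = out[:, IX["blood_d3g"]] / V_bl * drug.MW_D3G
    quantities = {
        "dap_plasma": dap_plasma,
        "d3g_plasma": d3g_plasma,
        "dap_urine": out[:, IX["urine_dap"]] * drug.MW_DAP / 1000.0,
        "d3g_urine": out[:, IX["urine_d3g"]] * drug.MW_D3G / 1000.0,
        "dap_feces": out[:, IX["feces_dap"]] * drug.MW_DAP / 1000.0,
        "rtg": rtg(dap_plasma, scenario.pd),
    }
    tc = TimeCourse(grid, quantities, label=scenario.label, states=out,
                    dose_umol=cum_dose)
    # cumulative UGE from the solved profile (no feedback on PK)
    from scipy.integrate import cumulative_trapezoid
    from .pharmacodynamics import uge_rate
    rate = uge_rate(phys.FPG, quantities["rtg"], phys.GFR)
    tc.quantities["uge"] = np.concatenate(
        [[0.0], cumulative_trapezoid(rate, grid)]) * MW_GLUCOSE / 1000.0
    tc.units["uge"] = "g"
    return tc


# ---------------------------------------------------------------------------
# parameter scans

_SCANNABLE_ROOTS = ("physiology", "drug", "pd")


def _with_param(scenario: Scenario, path: str, value: float) -> Scenario:
    """Return a copy of the scenario with one scalar replaced.

    Paths: ``drug.<field>``, ``physiology.<field>``, ``pd.<field>``, or
    ``dose_mg`` (sets the amount of every dose event).
    """
    if path == "dose_mg":
        doses = tuple(replace(d, amount=float(value)) for d in scenario.doses)
        return replace(scenario, doses=doses)
    root, _, attr = path.partition(".")
    if root not in _SCANNABLE_ROOTS or not attr:
        raise ValueError(f"unknown parameter path {path!r}")
    obj = getattr(scenario, root)
    if not hasattr(obj, attr):
        raise ValueError(f"unknown parameter path {path!r}")
    return replace(scenario, **{root: replace(obj, **{attr: float(value)})})


def _get_param(scenario: Scenario, path: str) -> float:
    if path == "dose_mg":
        if not scenario.doses:
            raise ValueError("scenario has no dose events")
        return scenario.doses[0].amount
    root, _, attr = path.partition(".")
    if root not in _SCANNABLE_ROOTS or not attr or not hasattr(getattr(scenario, root), attr):
        raise ValueError(f"unknown parameter path {path!r}")
    return float(getattr(getattr(scenario, root), attr))


class ScanResult(NamedTuple):
    value: float
    timecourse: TimeCourse
    pk: "_nca.PKResult"
    uge24: float


def parameter_scan(base: Scenario, param_path: str, values) -> list[ScanResult]:
    """One independent simulation per value; all other settings fixed.

    Returns, per value, the trajectory, the DAP plasma PK summary and the
    24 h urinary glucose excretion (g). Results do not depend on the
    order of ``values``.
    """
    results = []
    for v in values:
        sc = _with_param(base, param_path, v)
        tc = simulate(sc)
        dose_mg = sum(d.amount for d in sc.doses)
        pk = _nca.pk_summary(tc, "dap_plasma", dose_mg=dose_mg)
        uge24 = cumulative_uge(tc, sc.physiology, sc.pd, min(24.0, sc.t_end))
        results.append(ScanResult(float(v), tc, pk, uge24))
    return results


def run_study(study_config: dict) -> dict[str, TimeCourse]:
    """Simulate every arm of a study configuration.

    ``study_config`` mirrors the curated-study structure: a list of arms,
    each with physiology overrides (bodyweight, renal/hepatic class,
    prandial state, population, FPG) and a dosing regimen. Returns one
    trajectory per arm label.
    """
    from .io import scenario_from_config  # lazy: io imports TimeCourse

    arms = study_config.get("arms")
    if not isinstance(arms, list) or not arms:
        raise ValueError("study config must contain a non-empty 'arms' list")
    out: dict[str, TimeCourse] = {}
    for i, arm in enumerate(arms):
        label = arm.get("label", f"arm{i}")
        try:
            scenario = scenario_from_config({**arm, "label": label})
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed study arm {label!r}: {exc}") from exc
        if label in out:
            raise ValueError(f"duplicate arm label {label!r}")
        out[label] = simulate(scenario)
    return out
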