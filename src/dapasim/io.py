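"""Configuration schema and readers/writers.

Scenario and study configurations are JSON; time courses are tidy CSV
(columns ``time_h, quantity, value, unit``) written to 12 significant
digits; calibration datasets are CSV with columns
``time_h, mean, sd, n, observable, scenario_id``. Units are a fixed
dialect: h, ng/ml, mg, mM, g.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .calibration import StudyDataset
from .physiology import physiology_for
from .simulate import DoseEvent, QUANTITY_UNITS, Scenario, TimeCourse

__all__ = [
    "ScenarioConfig", "load_scenario", "scenario_from_config",
    "write_timecourse", "read_timecourse",
    "load_dataset", "write_runlog",
]

KNOWN_UNITS = set(QUANTITY_UNITS.values()) | {"h", ""}


class DoseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    time_h: float = Field(0.0, ge=0)
    route: Literal["oral", "iv"] = "oral"
    amount_mg: float = Field(..., ge=0)


class PhysiologyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bodyweight_kg: float = Field(75.0, gt=0)
    renal_class: str = "normal"
    hepatic_class: str = "none"
    prandial: str = "fasted"
    population: str = "healthy"
    fpg_mM: Optional[float] = Field(None, ge=0)


class PDConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rtg0_mM: Optional[float] = Field(None, gt=0)
    imax: Optional[float] = Field(None, ge=0, le=1)
    ic50_ng_ml: Optional[float] = Field(None, gt=0)


class DrugConfig(BaseModel):
    """Optional overrides of the reference drug parameters."""
    model_config = ConfigDict(extra="forbid")
    ka: Optional[float] = Field(None, gt=0)
    F_gut: Optional[float] = Field(None, ge=0, le=1)
    Kp_DAP: Optional[float] = Field(None, gt=0)
    Kp_rest: Optional[float] = Field(None, gt=0)
    Km: Optional[float] = Field(None, gt=0)
    Vmax_li: Optional[float] = Field(None, ge=0)
    f_ki_Vmax: Optional[float] = Field(None, ge=0)
    k_DAPEX_ki: Optional[float] = Field(None, ge=0)
    k_D3GEX_ki: Optional[float] = Field(None, ge=0)


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str = "scenario"
    physiology: PhysiologyConfig = PhysiologyConfig()
    drug: DrugConfig = DrugConfig()
    pd: PDConfig = PDConfig()
    doses: list[DoseConfig] = []
    t_end_h: float = Field(48.0, gt=0)
    output_grid_h: Optional[list[float]] = None


_PHYS_KEYS = set(PhysiologyConfig.model_fields)


def scenario_from_config(config: dict) -> Scenario:
    """Resolve a configuration mapping into a Scenario with defaults filled.

    Physiology keys may be given nested under ``physiology`` or flat at
    the top level (study-arm style). Drug/PD values default to the
    shipped reference parameterization.
    """
    from .reference import load_reference

    config = dict(config)
    phys_flat = {k: config.pop(k) for k in list(config) if k in _PHYS_KEYS}
    if phys_flat:
        nested = dict(config.get("physiology", {}))
        nested.update(phys_flat)
        config["physiology"] = nested
    try:
        cfg = ScenarioConfig.model_validate(config)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ValueError(f"invalid scenario config at {loc!r}: {first['msg']}") from exc

    ref_drug, ref_pd = load_reference()
    drug_overrides = {k: v for k, v in cfg.drug.model_dump().items() if v is not None}
    from dataclasses import replace as _replace
    drug = _replace(ref_drug, **drug_overrides) if drug_overrides else ref_drug
    pd_map = {"rtg0_mM": "RTG0", "imax": "Imax", "ic50_ng_ml": "IC50"}
    pd_overrides = {pd_map[k]: v for k, v in cfg.pd.model_dump().items() if v is not None}
    pd_params = _replace(ref_pd, **pd_overrides) if pd_overrides else ref_pd

    phys = physiology_for(
        BW=cfg.physiology.bodyweight_kg,
        renal_class=cfg.physiology.renal_class,
        hepatic_class=cfg.physiology.hepatic_class,
        prandial=cfg.physiology.prandial,
        population=cfg.physiology.population,
        fpg_mM=cfg.physiology.fpg_mM,
    )
    doses = tuple(DoseEvent(time=d.time_h, route=d.route, amount=d.amount_mg)
                  for d in sorted(cfg.doses, key=lambda d: d.time_h))
    return Scenario(
        physiology=phys, drug=drug, pd=pd_params, doses=doses,
        t_end=cfg.t_end_h,
        output_grid=tuple(cfg.output_grid_h) if cfg.output_grid_h else None,
        label=cfg.label)


def load_scenario(path: str | Path) -> Scenario:
    """Load and fully resolve a scenario JSON file."""
    path = Path(path)
    try:
        config = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path} is not valid JSON: {exc}") from exc
    return scenario_from_config(config)


def write_timecourse(tc: TimeCourse, path: str | Path) -> Path:
    """Write a TimeCourse as tidy CSV (12 significant digits)."""
    path = Path(path)
    frame = tc.to_frame()
    frame.to_csv(path, index=False, float_format="%.12g")
    return path


def read_timecourse(path: str | Path) -> TimeCourse:
    """Read a tidy time-course CSV back into a TimeCourse.

    Rejects out-of-order time grids and unknown unit strings.
    """
    frame = pd.read_csv(Path(path))
    required = {"time_h", "quantity", "value", "unit"}
    if not required.issubset(frame.columns):
        raise ValueError(f"time-course file must have columns {sorted(required)}")
    if frame.empty:
        return TimeCourse(np.array([]), {}, label=Path(path).stem)
    frame["unit"] = frame["unit"].fillna("")
    unknown = set(frame["unit"]) - KNOWN_UNITS
    if unknown:
        raise ValueError(f"unknown unit strings {sorted(unknown)}")
    quantities = {}
    units = {}
    time = None
    for name, group in frame.groupby("quantity", sort=False):
        t = group["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"series {name!r} has a non-increasing time grid")
        if time is None:
            time = t
        elif not np.array_equal(time, t):
            raise ValueError("all series must share one time grid")
        quantities[name] = group["value"].to_numpy(dtype=float)
        units[name] = group["unit"].iloc[0]
    return TimeCourse(time, quantities, units=units, label=Path(path).stem)


def load_dataset(csv_path: str | Path, scenarios: dict[str, Scenario]) -> StudyDataset:
    """Load a calibration dataset CSV against known scenarios."""
    frame = pd.read_csv(Path(csv_path))
    return StudyDataset(frame=frame, scenarios=scenarios)


def write_runlog(out_path: str | Path, **record) -> Path:
    """Write the per-invocation run log next to an output artifact."""
    from . import __version__

    out_path = Path(out_path)
    log_path = out_path.with_name(out_path.name + ".runlog.json")
    payload = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "package_version": __version__,
        "outputs": [str(out_path)],
        **record,
    }
    log_path.write_text(json.dumps(payload, indent=2, default=str))
    return log_path


def config_hash(path: str | Path) -> str:
    """Stable content hash of a configuration file, for the run log."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
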