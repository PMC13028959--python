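"""Reference parameterization of the model.

The kinetic constants that are not fixed from literature (absorption
rate, glucuronidation capacities, renal excretion constants, the rest-
compartment partition coefficient, and the PD parameters) are shipped as
a versioned JSON artifact produced by ``scripts/fit_reference.py``,
which calibrates them against the headline pharmacokinetic and
pharmacodynamic facts for dapagliflozin (terminal half-life ~13 h, Tmax
~3 h, oral bioavailability ~78%, urinary unchanged drug <2% of dose,
fed-state Cmax reduction in the 30–50% band).
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .pbpk import DrugParameters
from .pharmacodynamics import PDParameters
from .physiology import physiology_for
from .simulate import DoseEvent, Scenario

__all__ = [
    "load_reference", "reference_drug", "reference_pd", "reference_scenario",
]


@lru_cache(maxsize=1)
def _reference_payload() -> dict:
    path = resources.files("dapasim").joinpath("data/reference_parameters.json")
    return json.loads(path.read_text())


def load_reference() -> tuple[DrugParameters, PDParameters]:
    """Shipped reference (DrugParameters, PDParameters)."""
    payload = _reference_payload()
    return DrugParameters(**payload["drug"]), PDParameters(**payload["pd"])


def reference_drug() -> DrugParameters:
    return load_reference()[0]


def reference_pd() -> PDParameters:
    return load_reference()[1]


def reference_scenario(
    dose_mg: float = 10.0,
    route: str = "oral",
    t_end: float = 48.0,
    BW: float = 75.0,
    renal_class: str = "normal",
    hepatic_class: str = "none",
    prandial: str = "fasted",
    population: str = "healthy",
    fpg_mM: float | None = None,
    label: str | None = None,
    output_grid=None,
) -> Scenario:
    """Single-dose scenario with the reference parameterization."""
    drug, pd = load_reference()
    phys = physiology_for(BW=BW, renal_class=renal_class,
                          hepatic_class=hepatic_class, prandial=prandial,
                          population=population, fpg_mM=fpg_mM)
    doses = (DoseEvent(time=0.0, route=route, amount=dose_mg),) if dose_mg > 0 else ()
    return Scenario(
        physiology=phys, drug=drug, pd=pd, doses=doses, t_end=t_end,
        output_grid=output_grid,
        label=label or f"{dose_mg:g} mg {route} ({population}, {renal_class} renal)",
    )
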