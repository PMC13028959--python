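"""Shared fixtures: reference scenarios and reduced model limits."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from dapasim.pbpk import DrugParameters
from dapasim.pharmacodynamics import PDParameters
from dapasim.physiology import default_physiology
from dapasim.reference import load_reference, reference_scenario
from dapasim.simulate import DoseEvent, Scenario


@pytest.fixture(scope="session")
def reference_params() -> tuple[DrugParameters, PDParameters]:
    return load_reference()


@pytest.fixture(scope="session")
def oral_10mg() -> Scenario:
    """Single 10 mg oral dose, healthy fasted 75 kg subject, 96 h."""
    return reference_scenario(dose_mg=10.0, t_end=96.0)


@pytest.fixture(scope="session")
def iv_microdose() -> Scenario:
    """0.080 mg IV microdose with dense early sampling (IV study design)."""
    grid = tuple(np.concatenate([np.arange(0.0, 1.0, 0.01),
                                 np.arange(1.0, 96.001, 0.1)]))
    return reference_scenario(dose_mg=0.080, route="iv", t_end=96.0,
                              output_grid=grid)


def one_compartment_limit(k_ex: float = 10.0, flow_factor: float = 100.0,
                          dose_mg: float = 10.0) -> Scenario:
    """Scenario that collapses to a one-compartment model.

    No metabolism, no tissue partitioning (all Kp = 1), cardiac output
    scaled up so perfusion never limits exchange. The only elimination
    is first-order renal excretion from the kidney, so the closed-form
    solution has CL = k_ex * V_ki and V = body volume. Dosing is oral
    (complete absorption) so the profile is smooth on the output grid;
    an IV bolus into the small blood pool would put a sub-grid
    distribution spike under the trapezoid.
    """
    phys = default_physiology(75.0)
    phys = replace(phys, CO=phys.CO * flow_factor)
    drug = DrugParameters(ka=2.0, Vmax_li=0.0, f_ki_Vmax=0.0,
                          k_DAPEX_ki=k_ex, k_D3GEX_ki=1.0,
                          Kp_DAP=1.0, Kp_rest=1.0, F_gut=1.0)
    pd_params = PDParameters(RTG0=10.0, Imax=0.5, IC50=10.0)
    return Scenario(physiology=phys, drug=drug, pd=pd_params,
                    doses=(DoseEvent(0.0, "oral", dose_mg),), t_end=96.0,
                    label="one-compartment limit")
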