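"""Pharmacodynamics: renal glucose threshold (RTG) and urinary glucose
excretion (UGE).

SGLT2 inhibition by dapagliflozin lowers the renal threshold for glucose.
The threshold responds to total plasma drug concentration through a
saturable Emax-type relation,

    RTG(C) = RTG0 * (1 - Imax * C / (IC50 + C)),

and glucosuria is the filtered glucose exceeding the threshold,

    UGE rate = GFR * max(0, FPG - RTG)    [mmol/h].

Renal filtration and tubular reabsorption are not modeled explicitly;
the threshold representation absorbs the reabsorption capacity. Plasma
glucose is held constant at the scenario's fasting value (no diurnal
variation), and the drug's pharmacokinetics do not depend on glucose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .pbpk import MW_GLUCOSE
from .physiology import PhysiologyState

__all__ = ["PDParameters", "rtg", "uge_rate", "cumulative_uge"]


@dataclass(frozen=True)
class PDParameters:
    RTG0: float   # baseline renal threshold for glucose, mM
    Imax: float   # maximal fractional threshold reduction, in [0, 1]
    IC50: float   # plasma DAP at half-maximal reduction, ng/mL

    def __post_init__(self) -> None:
        if self.RTG0 <= 0:
            raise ValueError(f"RTG0 must be positive, got {self.RTG0}")
        if not 0.0 <= self.Imax <= 1.0:
            raise ValueError(f"Imax must lie in [0, 1], got {self.Imax}")
        if self.IC50 <= 0:
            raise ValueError(f"IC50 must be positive, got {self.IC50}")


def rtg(C_dap, pd: PDParameters):
    """Renal glucose threshold (mM) at plasma DAP concentration(s) (ng/mL)."""
    C = np.asarray(C_dap, dtype=float)
    if np.any(C < 0):
        raise ValueError("plasma concentration must be non-negative")
    out = pd.RTG0 * (1.0 - pd.Imax * C / (pd.IC50 + C))
    return float(out) if np.isscalar(C_dap) else out


def uge_rate(FPG, RTG, GFR):
    """Urinary glucose excretion rate, mmol/h.

    Filtered glucose above the renal threshold is excreted:
    ``GFR * max(0, FPG - RTG)`` with FPG and RTG in mM and GFR in L/h.
    """
    return GFR * np.maximum(0.0, np.asarray(FPG, dtype=float) - np.asarray(RTG, dtype=float))


def cumulative_uge(traj, phys: PhysiologyState, pd: PDParameters,
                   horizon_h: float) -> float:
    """Cumulative urinary glucose excretion (grams) up to ``horizon_h``.

    Integrates the UGE rate along the simulated plasma DAP profile by
    trapezoidal quadrature on the trajectory's output grid.
    """
    t = np.asarray(traj.time)
    if horizon_h > t[-1] + 1e-9:
        raise ValueError(
            f"horizon {horizon_h} h exceeds trajectory span {t[-1]} h")
    C = np.asarray(traj["dap_plasma"])
    rate = uge_rate(phys.FPG, rtg(C, pd), phys.GFR)  # mmol/h
    cum_mmol = np.concatenate([[0.0], cumulative_trapezoid(rate, t)])
    cum_at = float(np.interp(horizon_h, t, cum_mmol))
    return cum_at * MW_GLUCOSE / 1000.0  # mmol -> g
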