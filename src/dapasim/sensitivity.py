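"""Local normalized sensitivity analysis of PK/PD readouts.

Each parameter is perturbed by ±1% around its reference value and the
readout response is measured by the symmetric midpoint difference,
normalized to a dimensionless elasticity:

    Snorm(q, p) = [q(1.01 p) - q(0.99 p)] / (0.02 p) * p / q(p),

i.e. relative change in output per relative change in parameter.
Readouts are AUCinf, Cmax and terminal half-life of drug and metabolite
plus 24 h urinary glucose excretion. Rows whose sensitivities all stay
below a threshold (default 0.1 in absolute value) are dropped for
reporting, and the remaining rows are ordered by single-linkage
hierarchical clustering on Euclidean row distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from . import nca as _nca
from .pharmacodynamics import cumulative_uge
from .simulate import Scenario, _get_param, _with_param, simulate

__all__ = ["SensitivityMatrix", "local_sensitivity", "filter_and_cluster",
           "READOUTS", "DEFAULT_PARAM_SET"]

READOUTS = ("AUC_DAP", "Cmax_DAP", "thalf_DAP",
            "AUC_D3G", "Cmax_D3G", "thalf_D3G", "UGE24")

#: Estimable parameter set: kinetic, physiological and PD parameters.
#: Physical constants (molar masses), unit conversions and dosing are excluded.
DEFAULT_PARAM_SET = (
    "drug.ka", "drug.F_gut", "drug.Kp_DAP", "drug.Kp_rest", "drug.Km",
    "drug.Vmax_li", "drug.f_ki_Vmax", "drug.k_DAPEX_ki", "drug.k_D3GEX_ki",
    "physiology.BW", "physiology.CO", "physiology.GFR_ref",
    "physiology.f_renal", "physiology.f_absorption",
    "pd.RTG0", "pd.Imax", "pd.IC50",
)


@dataclass
class SensitivityMatrix:
    """Normalized sensitivities: rows parameters, columns readouts.

    Entries are NaN where the reference readout is zero (normalization
    undefined, flagged rather than silently zero).
    """

    params: tuple[str, ...]
    readouts: tuple[str, ...]
    values: np.ndarray
    perturbation: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.params), len(self.readouts)):
            raise ValueError("sensitivity matrix shape mismatch")
        if self.perturbation <= 0:
            raise ValueError("perturbation must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.params),
                            columns=list(self.readouts))

    def __getitem__(self, key: tuple[str, str]) -> float:
        p, q = key
        return float(self.values[self.params.index(p), self.readouts.index(q)])


def _readout_vector(scenario: Scenario, uge_fpg: float | None) -> np.ndarray:
    tc = simulate(scenario)
    dap = _nca.pk_summary(tc, "dap_plasma")
    d3g = _nca.pk_summary(tc, "d3g_plasma")
    phys = scenario.physiology if uge_fpg is None else replace(
        scenario.physiology, FPG=uge_fpg)
    uge24 = cumulative_uge(tc, phys, scenario.pd, min(24.0, scenario.t_end))
    return np.array([dap.auc_inf, dap.cmax, dap.thalf,
                     d3g.auc_inf, d3g.cmax, d3g.thalf, uge24])


def local_sensitivity(base: Scenario, param_set=DEFAULT_PARAM_SET,
                      delta: float = 0.01,
                      uge_fpg: float | None = 7.5) -> SensitivityMatrix:
    """Symmetric-midpoint normalized sensitivities around a scenario.

    ``uge_fpg`` sets the plasma glucose used for the UGE24 readout
    (default 7.5 mM, the diabetic band); pass None to keep the
    scenario's own value. Parameters whose reference value is zero have
    no relative perturbation and report zero sensitivity.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    q0 = _readout_vector(base, uge_fpg)
    rows = []
    for path in param_set:
        p0 = _get_param(base, path)
        if p0 == 0.0:
            rows.append(np.zeros(len(READOUTS)))
            continue
        q_hi = _readout_vector(_with_param(base, path, p0 * (1 + delta)), uge_fpg)
        q_lo = _readout_vector(_with_param(base, path, p0 * (1 - delta)), uge_fpg)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (q_hi - q_lo) / (2.0 * delta) / q0
        s = np.where(q0 == 0.0, np.nan, s)
        rows.append(s)
    return SensitivityMatrix(tuple(param_set), READOUTS, np.array(rows), delta)


def filter_and_cluster(S: SensitivityMatrix,
                       threshold: float = 0.1) -> SensitivityMatrix:
    """Drop weakly influential rows, order the rest by single linkage.

    Rows with all |Snorm| < threshold (undefined entries treated as
    no-effect) are removed; the remaining rows are reordered by the
    leaf order of a single-linkage dendrogram on Euclidean row distance.
    """
    vals = np.nan_to_num(S.values, nan=0.0)
    keep = np.where(np.any(np.abs(vals) >= threshold, axis=1))[0]
    if keep.size == 0:
        warnings.warn("all sensitivities below threshold; empty matrix",
                      stacklevel=2)
        return SensitivityMatrix((), S.readouts,
                                 np.empty((0, len(S.readouts))), S.perturbation)
    if keep.size == 1:
        order = keep
    else:
        Z = linkage(vals[keep], method="single", metric="euclidean")
        order = keep[leaves_list(Z)]
    return SensitivityMatrix(tuple(S.params[i] for i in order), S.readouts,
                             S.values[order], S.perturbation)
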