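"""ODE core: coupled disposition of dapagliflozin (DAP) and its
glucuronide metabolite (D3G) across a whole-body compartment structure.

Compartments and routes
-----------------------
Oral doses are split instantaneously at administration: a fraction
``F_gut`` enters the gut lumen and is available for first-order
absorption (rate ``ka * f_absorption``) into the enterocyte pool, from
which drug is handed to the portal circulation and carried into the
liver (first pass); the complement ``1 - F_gut`` is routed to a fecal
transit pool and appears in feces with a slow first-order rate, so the
fecal fraction of dose is fixed by construction. IV doses enter the
blood pool directly. Gut tissue itself takes part only in systemic
flow-limited distribution; the absorbed flux does not equilibrate with
it on the way in (enterocyte-to-portal transit is fast).

Distribution is flow-limited with instantaneous tissue partitioning:
tissue venous concentration equals ``C_tissue / Kp``. Transport of drug
in liver and kidney is fast and reversible relative to metabolism, hence
not represented by explicit transporter states.

DAP is glucuronidated irreversibly to D3G by UGT1A9 in liver and kidney,
each following Michaelis–Menten kinetics with a shared ``Km``; the
hepatic capacity scales with functional parenchyma ``(1 - f_cirrhosis)``
and the same fraction of hepatic inflow is shunted past the liver.
DAP and D3G are excreted into urine from kidney tissue by first-order
processes scaled by ``f_renal``. D3G does not partition into tissues
(Kp = 1) and is confined to the blood pool and kidney.

All state amounts are in µmol; concentrations derived as µmol/L (= µM),
reported in ng/mL via the molar masses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physiology import PhysiologyState

__all__ = [
    "DrugParameters",
    "build_rhs",
    "mm_rate",
    "mass_balance",
    "STATE_NAMES",
    "N_STATES",
    "MW_DAP",
    "MW_D3G",
    "MW_GLUCOSE",
]

#: Molar masses, g/mol (standard chemistry references).
MW_DAP = 408.87
MW_D3G = 585.03
MW_GLUCOSE = 180.16

#: First-order appearance rate of the fecal transit pool in feces, 1/h.
K_FECES_TRANSIT = 0.05

#: Enterocyte-to-portal transit rate, 1/h (~10 min; fast, not rate-limiting).
K_ENTEROCYTE = 6.0

# State vector layout (amounts in µmol).
STATE_NAMES = (
    "lumen_dap",          # gut lumen, absorbable oral dose
    "feces_transit_dap",  # fecal route in transit
    "feces_dap",          # cumulative fecal excretion
    "enterocyte_dap",     # absorption site, drains into the portal inflow
    "gut_dap",            # gut tissue (systemic distribution only)
    "blood_dap",          # lumped venous+arterial plasma-accessible pool
    "liver_dap",
    "kidney_dap",
    "lung_dap",
    "rest_dap",
    "urine_dap",          # cumulative urinary excretion, unchanged drug
    "blood_d3g",
    "kidney_d3g",
    "urine_d3g",          # cumulative urinary excretion of the metabolite
)
N_STATES = len(STATE_NAMES)
IX = {name: i for i, name in enumerate(STATE_NAMES)}


@dataclass(frozen=True)
class DrugParameters:
    """Absorption, partitioning, metabolic, and excretion constants.

    ``Kp_DAP`` applies to the explicitly modeled organs (gut, liver,
    kidney, lung); the lumped rest-of-body compartment carries its own
    coefficient ``Kp_rest``. The metabolite does not partition
    (``Kp_D3G = 1``).
    """

    ka: float                 # first-order absorption rate, 1/h
    Vmax_li: float            # maximal hepatic DAP→D3G rate, µmol/h per L liver
    f_ki_Vmax: float          # kidney-to-liver scaling of Vmax, dimensionless
    k_DAPEX_ki: float         # first-order renal excretion of DAP, 1/h
    k_D3GEX_ki: float         # first-order renal excretion of D3G, 1/h
    F_gut: float = 0.84       # fraction of oral dose entering absorption
    Kp_DAP: float = 25.52     # tissue-to-plasma partition coefficient (organs)
    Kp_rest: float = 1.0      # partition coefficient of the rest compartment
    Kp_D3G: float = 1.0       # metabolite partition coefficient
    Km: float = 479.0         # Michaelis constant for DAP→D3G, µM
    MW_DAP: float = MW_DAP    # g/mol
    MW_D3G: float = MW_D3G    # g/mol

    def __post_init__(self) -> None:
        for name in ("ka", "Vmax_li", "f_ki_Vmax", "k_DAPEX_ki", "k_D3GEX_ki",
                     "Kp_DAP", "Kp_rest", "Kp_D3G"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.F_gut <= 1.0:
            raise ValueError(f"F_gut must lie in [0, 1], got {self.F_gut}")
        if self.Km <= 0:
            raise ValueError(f"Km must be positive, got {self.Km}")


def mm_rate(C: float, Vmax: float, Km: float) -> float:
    """Irreversible Michaelis–Menten rate ``Vmax * C / (Km + C)``.

    ``C`` and ``Km`` in µM, ``Vmax`` in µmol/h.
    """
    if Km <= 0:
        raise ValueError(f"Km must be positive, got {Km}")
    if np.any(np.asarray(C) < 0) or Vmax < 0:
        raise ValueError("concentration and Vmax must be non-negative")
    return Vmax * C / (Km + C)


def build_rhs(phys: PhysiologyState, drug: DrugParameters):
    """Return the vector field ``f(t, y) -> dy/dt`` for the drug states.

    The returned callable is pure and closes over pre-computed absolute
    volumes and flows; glucose pharmacodynamics are evaluated separately
    from the solved trajectory and do not feed back on the drug states.
    """
    V_gu, V_ki, V_li, V_lu, V_bl, V_re = (
        phys.V_gu, phys.V_ki, phys.V_li, phys.V_lu, phys.V_bl, phys.V_re)
    Q_gu, Q_ki, Q_ha, Q_h, Q_lu, Q_re = (
        phys.Q_gu, phys.Q_ki, phys.Q_ha, phys.Q_h, phys.Q_lu, phys.Q_re)
    Kp = drug.Kp_DAP
    Kp_re = drug.Kp_rest
    Km = drug.Km
    ka_eff = drug.ka * phys.f_absorption
    f_liver = 1.0 - phys.f_cirrhosis          # functional parenchyma fraction
    vmax_li = drug.Vmax_li * f_liver * V_li   # µmol/h
    vmax_ki = drug.Vmax_li * drug.f_ki_Vmax * V_ki
    k_dapex = drug.k_DAPEX_ki * phys.f_renal
    k_d3gex = drug.k_D3GEX_ki * phys.f_renal

    f_cirr = phys.f_cirrhosis

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        C_gu = y[4] / V_gu
        C_bl = y[5] / V_bl
        C_li = y[6] / V_li
        C_ki = y[7] / V_ki
        C_lu = y[8] / V_lu
        C_re = y[9] / V_re
        C_bl_d3g = y[11] / V_bl
        C_ki_d3g = y[12] / V_ki

        r_abs = ka_eff * y[0]
        r_portal = K_ENTEROCYTE * y[3]
        r_fec = K_FECES_TRANSIT * y[1]

        # Hepatic inflow: arterial + portal (gut venous + absorbed flux);
        # the shunted fraction bypasses the liver into the blood pool.
        inflow_li = Q_ha * C_bl + Q_gu * C_gu / Kp + r_portal
        r_met_li = vmax_li * C_li / (Km + C_li)
        r_met_ki = vmax_ki * C_ki / (Km + C_ki)
        r_ex_dap = k_dapex * y[7]
        r_ex_d3g = k_d3gex * y[12]

        dy = np.empty(N_STATES)
        dy[0] = -r_abs
        dy[1] = -r_fec
        dy[2] = r_fec
        dy[3] = r_abs - r_portal
        dy[4] = Q_gu * (C_bl - C_gu / Kp)
        dy[5] = (
            Q_lu * (C_lu / Kp - C_bl)
            + Q_ki * (C_ki / Kp - C_bl)
            + Q_re * (C_re / Kp_re - C_bl)
            - Q_gu * C_bl
            - Q_ha * C_bl
            + f_liver * Q_h * C_li / Kp
            + f_cirr * inflow_li
        )
        dy[6] = f_liver * inflow_li - f_liver * Q_h * C_li / Kp - r_met_li
        dy[7] = Q_ki * (C_bl - C_ki / Kp) - r_met_ki - r_ex_dap
        dy[8] = Q_lu * (C_bl - C_lu / Kp)
        dy[9] = Q_re * (C_bl - C_re / Kp_re)
        dy[10] = r_ex_dap
        dy[11] = r_met_li - Q_ki * (C_bl_d3g - C_ki_d3g)
        dy[12] = r_met_ki + Q_ki * (C_bl_d3g - C_ki_d3g) - r_ex_d3g
        dy[13] = r_ex_d3g
        return dy

    return rhs


def mass_balance(traj, dose_umol: float | None = None) -> float:
    """Maximum relative error of molar mass conservation along a trajectory.

    Total DAP-equivalents (all DAP amounts + all D3G amounts + urine +
    feces) must equal the administered dose at every reported time point;
    returns ``max_t |total(t) - dose(t)| / dose`` (defined as 0 for a
    zero dose). For multi-dose trajectories pass ``dose_umol=None`` to
    compare against the cumulative administered dose that
    :func:`dapasim.simulate.simulate` records on the trajectory.

    ``traj`` is a TimeCourse produced by the simulator, which retains the
    raw state matrix.
    """
    states = np.asarray(traj.states)
    total = states.sum(axis=1)
    ref = np.asarray(traj.dose_umol) if dose_umol is None else np.full_like(total, dose_umol)
    scale = float(np.max(ref, initial=0.0))
    if scale == 0:
        return float(np.max(np.abs(total), initial=0.0))
    return float(np.max(np.abs(total - ref)) / scale)
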