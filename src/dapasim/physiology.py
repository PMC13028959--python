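"""Subject-level physiology for the whole-body PBPK/PD model.

The model describes a typical individual by body weight, fractional organ
volumes and blood flows, cardiac output, glomerular filtration, and three
dimensionless scaling factors capturing pathophysiology and prandial state:

* ``f_renal`` — renal function relative to normal (KDIGO categories),
  applied to GFR and to the renal excretion of drug and metabolite;
* ``f_cirrhosis`` — cirrhosis severity (Child–Turcotte–Pugh classes),
  interpreted as the fraction of hepatic function lost and of hepatic
  inflow shunted past the liver;
* ``f_absorption`` — intestinal absorption activity (fed state slows
  gastric emptying, reducing the effective absorption rate).

Organ volumes and flows are obtained by scaling fractional values with
body weight (1 kg tissue ≈ 1 L). Fractions not reported for the named
organs are closed into a lumped blood pool and a rest-of-body compartment
so that volumes and flows each sum exactly to the whole body.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "PhysiologyState",
    "default_physiology",
    "renal_factor",
    "hepatic_factor",
    "prandial_factor",
    "default_fpg",
    "physiology_for",
    "RENAL_FACTORS",
    "HEPATIC_FACTORS",
    "PRANDIAL_FACTORS",
    "FPG_DEFAULTS_MM",
]

# Fractional organ volumes (dimensionless, of body weight).
FV_GUT = 0.0171
FV_KIDNEY = 0.0044
FV_LIVER = 0.0210
FV_LUNG = 0.0076
#: Plasma-accessible blood pool (venous + arterial), volume closure constant.
FV_BLOOD = 0.0786

# Fractional blood flows (dimensionless, of cardiac output).
FQ_GUT = 0.18
FQ_KIDNEY = 0.19
FQ_HEPATIC = 0.215  # hepatic venous outflow = hepatic artery + portal (gut) inflow
FQ_LUNG = 1.0

#: Cardiac output at the reference body weight, L/h (resting adult).
CO_REF_L_PER_H = 108.0
BW_REF_KG = 70.0

#: Glomerular filtration rate at f_renal = 1, L/h (~108 mL/min).
GFR_REF_L_PER_H = 6.5

#: KDIGO-mapped renal function factors.
RENAL_FACTORS = {"normal": 1.00, "mild": 0.69, "moderate": 0.32, "severe": 0.19}

#: Child–Turcotte–Pugh-mapped cirrhosis severity factors.
HEPATIC_FACTORS = {"none": 0.0, "CTP_A": 0.40, "CTP_B": 0.70, "CTP_C": 0.80}

#: Prandial-state absorption activity factors.
PRANDIAL_FACTORS = {"fasted": 1.0, "fed": 0.3}

#: Default fasting plasma glucose by population, mM.
FPG_DEFAULTS_MM = {"healthy": 5.0, "T1DM": 7.5, "T2DM": 7.5}


@dataclass(frozen=True)
class PhysiologyState:
    """Physiological parameter set consumed by the ODE core.

    Volumes are fractions of body weight, flows fractions of cardiac
    output. Derived absolute quantities are exposed as properties.
    """

    BW: float  # body mass, kg
    FVgu: float = FV_GUT
    FVki: float = FV_KIDNEY
    FVli: float = FV_LIVER
    FVlu: float = FV_LUNG
    FVbl: float = FV_BLOOD
    FQgu: float = FQ_GUT
    FQki: float = FQ_KIDNEY
    FQh: float = FQ_HEPATIC
    FQlu: float = FQ_LUNG
    CO: float = CO_REF_L_PER_H  # L/h, set by default_physiology via BW scaling
    GFR_ref: float = GFR_REF_L_PER_H  # L/h at f_renal = 1
    f_renal: float = 1.0
    f_cirrhosis: float = 0.0
    f_absorption: float = 1.0
    FPG: float = FPG_DEFAULTS_MM["healthy"]  # mM

    def __post_init__(self) -> None:
        if self.BW <= 0:
            raise ValueError(f"body weight must be positive, got {self.BW}")
        fractions = (self.FVgu, self.FVki, self.FVli, self.FVlu, self.FVbl,
                     self.FQgu, self.FQki, self.FQh, self.FQlu)
        if any(f < 0 for f in fractions):
            raise ValueError("fractional volumes and flows must be non-negative")
        if self.FVgu + self.FVki + self.FVli + self.FVlu + self.FVbl > 1.0 + 1e-12:
            raise ValueError("fractional organ volumes exceed the whole body")
        if self.FQh < self.FQgu:
            raise ValueError("hepatic venous outflow fraction below gut inflow fraction")
        if self.FQh + self.FQki > 1.0 + 1e-12:
            raise ValueError("fractional blood flows exceed cardiac output")
        if not 0.0 <= self.f_renal <= 1.0:
            raise ValueError(f"f_renal must lie in [0, 1], got {self.f_renal}")
        if not 0.0 <= self.f_cirrhosis <= 1.0:
            raise ValueError(f"f_cirrhosis must lie in [0, 1], got {self.f_cirrhosis}")
        if self.f_absorption <= 0:
            raise ValueError(f"f_absorption must be positive, got {self.f_absorption}")
        if self.CO <= 0 or self.GFR_ref < 0:
            raise ValueError("cardiac output must be positive and GFR non-negative")
        if self.FPG < 0:
            raise ValueError(f"plasma glucose must be non-negative, got {self.FPG}")

    # --- volume closure -------------------------------------------------
    @property
    def FVre(self) -> float:
        """Rest-of-body volume fraction: closes volumes to exactly 1."""
        return 1.0 - (self.FVgu + self.FVki + self.FVli + self.FVlu + self.FVbl)

    @property
    def FQre(self) -> float:
        """Rest-of-body flow fraction: closes systemic flows to cardiac output."""
        return 1.0 - self.FQh - self.FQki

    @property
    def FQha(self) -> float:
        """Hepatic arterial inflow fraction (hepatic outflow minus portal)."""
        return self.FQh - self.FQgu

    # --- absolute volumes (L; 1 kg tissue = 1 L) ------------------------
    @property
    def V_gu(self) -> float:
        return self.FVgu * self.BW

    @property
    def V_ki(self) -> float:
        return self.FVki * self.BW

    @property
    def V_li(self) -> float:
        return self.FVli * self.BW

    @property
    def V_lu(self) -> float:
        return self.FVlu * self.BW

    @property
    def V_bl(self) -> float:
        return self.FVbl * self.BW

    @property
    def V_re(self) -> float:
        return self.FVre * self.BW

    # --- absolute flows (L/h) -------------------------------------------
    @property
    def Q_gu(self) -> float:
        return self.FQgu * self.CO

    @property
    def Q_ki(self) -> float:
        return self.FQki * self.CO

    @property
    def Q_h(self) -> float:
        return self.FQh * self.CO

    @property
    def Q_ha(self) -> float:
        return self.FQha * self.CO

    @property
    def Q_lu(self) -> float:
        return self.FQlu * self.CO

    @property
    def Q_re(self) -> float:
        return self.FQre * self.CO

    @property
    def GFR(self) -> float:
        """Effective glomerular filtration rate, L/h."""
        return self.GFR_ref * self.f_renal


def default_physiology(BW: float = 75.0) -> PhysiologyState:
    """Healthy fasted reference physiology at a given body weight (kg).

    Cardiac output scales linearly with body weight from the 70 kg
    reference value.
    """
    if BW <= 0:
        raise ValueError(f"body weight must be positive, got {BW}")
    return PhysiologyState(BW=BW, CO=CO_REF_L_PER_H * BW / BW_REF_KG)


def _lookup(mapping: dict, key: str, what: str) -> float:
    try:
        return mapping[key]
    except KeyError:
        raise ValueError(
            f"unknown {what} {key!r}; expected one of {sorted(mapping)}"
        ) from None


def renal_factor(renal_class: str) -> float:
    """Renal function factor for a KDIGO category (normal/mild/moderate/severe)."""
    return _lookup(RENAL_FACTORS, renal_class, "renal class")


def hepatic_factor(hepatic_class: str) -> float:
    """Cirrhosis severity factor for a Child–Turcotte–Pugh class (none/CTP_A/B/C)."""
    return _lookup(HEPATIC_FACTORS, hepatic_class, "hepatic class")


def prandial_factor(prandial: str) -> float:
    """Absorption activity factor for a prandial state (fasted/fed)."""
    return _lookup(PRANDIAL_FACTORS, prandial, "prandial state")


def default_fpg(population: str) -> float:
    """Default fasting plasma glucose (mM) for a population label."""
    return _lookup(FPG_DEFAULTS_MM, population, "population")


def physiology_for(
    BW: float = 75.0,
    renal_class: str = "normal",
    hepatic_class: str = "none",
    prandial: str = "fasted",
    population: str = "healthy",
    fpg_mM: float | None = None,
) -> PhysiologyState:
    """Build a PhysiologyState from subject-level covariates.

    A study-specific ``fpg_mM`` overrides the population default.
    """
    base = default_physiology(BW)
    return replace(
        base,
        f_renal=renal_factor(renal_class),
        f_cirrhosis=hepatic_factor(hepatic_class),
        f_absorption=prandial_factor(prandial),
        FPG=default_fpg(population) if fpg_mM is None else float(fpg_mM),
    )
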