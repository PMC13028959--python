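"""Non-compartmental PK analysis of concentration–time profiles.

Standard model-free metrics: AUC by the linear-up/log-down trapezoid
with C_last/lambda_z extrapolation to infinity, Cmax/Tmax read off the
grid, terminal half-life from a log-linear regression whose window is
chosen by best adjusted R² over the last 3–10 points (Tmax excluded),
and excretion fractions from cumulative urine/feces series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKResult", "auc", "half_life", "terminal_fit",
    "excretion_fractions", "bioavailability", "pk_summary",
]


@dataclass
class PKResult:
    """NCA summary for one analyte profile.

    Concentrations in ng/mL, times in h, fractions in % of dose.
    ``auc_inf`` and ``thalf`` are NaN when no terminal log-linear phase
    is identifiable; ``F_oral`` is filled by :func:`bioavailability`.
    """

    auc_0_t: float
    auc_inf: float
    cmax: float
    tmax: float
    thalf: float
    dose_mg: float = float("nan")
    frac_urine_unchanged: float = float("nan")
    frac_feces: float = float("nan")
    F_oral: float = float("nan")
    lambda_z: float = float("nan")
    n_terminal: int = 0
    r2_adj: float = float("nan")


def _check_profile(time, conc):
    t = np.asarray(time, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("time and concentration must be 1-D arrays of equal length")
    if len(t) < 3:
        raise ValueError("profile needs at least 3 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return t, c


def _auc_linlog(t: np.ndarray, c: np.ndarray) -> float:
    """Linear-up/log-down trapezoid over the whole profile."""
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    down = (c2 < c1) & (c2 > 0)
    seg = 0.5 * (c1 + c2)  # linear up (and across equal/zero values)
    if np.any(down):
        seg = seg.copy()
        seg[down] = (c1[down] - c2[down]) / np.log(c1[down] / c2[down])
    return float(np.sum(seg * dt))


def terminal_fit(time, conc, n_min: int = 3, n_max: int = 10):
    """Select the terminal log-linear window and fit lambda_z.

    Candidate windows are the last ``n`` points (``n_min <= n <= n_max``)
    strictly after Tmax with positive concentrations; the window with the
    highest adjusted R² and a negative slope wins. Returns
    ``(lambda_z, n, r2_adj)`` or ``None`` when no window qualifies.
    """
    t, c = _check_profile(time, conc)
    i_max = int(np.argmax(c))
    t_tail = t[i_max + 1:]
    c_tail = c[i_max + 1:]
    pos = c_tail > 0
    t_tail, c_tail = t_tail[pos], c_tail[pos]
    best = None
    for n in range(n_min, min(n_max, len(t_tail)) + 1):
        tt, cc = t_tail[-n:], np.log(c_tail[-n:])
        slope, intercept = np.polyfit(tt, cc, 1)
        if slope >= 0:
            continue
        resid = cc - (slope * tt + intercept)
        ss_tot = float(np.sum((cc - cc.mean()) ** 2))
        if ss_tot == 0:
            continue
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if best is None or r2_adj > best[2]:
            best = (-slope, n, r2_adj)
    return best


def auc(time, conc) -> tuple[float, float]:
    """AUC to the last point and extrapolated to infinity (conc·h units).

    ``auc_inf`` is NaN when the terminal fit is unavailable (fewer than
    three positive declining points after Tmax); both are 0 for an
    all-zero profile.
    """
    t, c = _check_profile(time, conc)
    if np.all(c == 0):
        return 0.0, 0.0
    auc_0_t = _auc_linlog(t, c)
    fit = terminal_fit(t, c)
    if fit is None:
        return auc_0_t, float("nan")
    lam = fit[0]
    c_last = c[c > 0][-1]
    return auc_0_t, auc_0_t + float(c_last) / lam


def half_life(time, conc) -> float:
    """Terminal half-life ln(2)/lambda_z from the log-linear tail."""
    fit = terminal_fit(time, conc)
    if fit is None:
        raise ValueError(
            "no identifiable terminal log-linear phase (need >= 3 positive "
            "declining points after Tmax)")
    return float(np.log(2.0) / fit[0])


def excretion_fractions(traj, dose_mg: float) -> tuple[float, float]:
    """Percent of dose excreted unchanged in urine and in feces.

    Uses the final values of the trajectory's cumulative ``dap_urine``
    and ``dap_feces`` series (mg).
    """
    if dose_mg <= 0:
        raise ValueError("excretion fractions are undefined for a zero dose")
    urine = 100.0 * float(traj["dap_urine"][-1]) / dose_mg
    feces = 100.0 * float(traj["dap_feces"][-1]) / dose_mg
    return urine, feces


def bioavailability(oral: PKResult, iv: PKResult) -> float:
    """Absolute oral bioavailability, %, from dose-normalized AUC ratio."""
    for res, name in ((oral, "oral"), (iv, "iv")):
        if not np.isfinite(res.auc_inf):
            raise ValueError(f"{name} profile has no extrapolated AUC")
        if not np.isfinite(res.dose_mg) or res.dose_mg <= 0:
            raise ValueError(f"{name} profile has no positive dose")
    return 100.0 * (oral.auc_inf / oral.dose_mg) / (iv.auc_inf / iv.dose_mg)


def pk_summary(traj, quantity: str = "dap_plasma",
               dose_mg: float = float("nan")) -> PKResult:
    """Full NCA summary of one plasma series of a TimeCourse.

    Excretion fractions are filled for the parent drug when cumulative
    urine/feces series are present and a dose is given.
    """
    t = np.asarray(traj.time)
    c = np.asarray(traj[quantity])
    auc_0_t, auc_inf = auc(t, c)
    fit = terminal_fit(t, c)
    res = PKResult(
        auc_0_t=auc_0_t,
        auc_inf=auc_inf,
        cmax=float(np.max(c)),
        tmax=float(t[int(np.argmax(c))]),
        thalf=float(np.log(2.0) / fit[0]) if fit else float("nan"),
        dose_mg=float(dose_mg),
        lambda_z=fit[0] if fit else float("nan"),
        n_terminal=fit[1] if fit else 0,
        r2_adj=fit[2] if fit else float("nan"),
    )
    if quantity == "dap_plasma" and np.isfinite(dose_mg) and dose_mg > 0 \
            and "dap_urine" in traj and "dap_feces" in traj:
        res.frac_urine_unchanged, res.frac_feces = excretion_fractions(traj, dose_mg)
    return res
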