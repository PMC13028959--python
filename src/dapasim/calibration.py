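"""Weighted least-squares parameter estimation against study-format data.

The objective is

    F(p) = 1/2 * sum_{i,k} w_{i,k} * r_{i,k}(p)^2,     w_{i,k} = n_k / sigma_{i,k},

summing over time courses ``k`` (scenario × observable) and time points
``i``: residuals between model predictions and observed means are
weighted by the study group size and the inverse of the reported
standard deviation. Estimation runs a bounded local least-squares
optimizer (trust-region reflective on log10-transformed parameters)
from many starting points drawn log-uniformly within bounds
(multistart), sequentially: pharmacokinetic parameters first, then
pharmacodynamic parameters with PK fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .simulate import Scenario, _with_param, simulate

__all__ = [
    "StudyDataset", "ParameterSpace", "FitResult",
    "cost", "residuals", "multistart_fit", "goodness_of_fit",
    "PK_STAGE_BOUNDS", "PD_STAGE_BOUNDS",
]

logger = logging.getLogger(__name__)

#: Solver tolerances used inside the fitting loop (looser than reporting
#: runs for speed; the optimum is insensitive at these data densities).
FIT_RTOL = 1e-6
FIT_ATOL = 1e-9

#: Penalty cost returned when a parameter vector cannot be simulated.
PENALTY_COST = 1e12

#: Physiologic default bounds for the estimable PK parameters.
PK_STAGE_BOUNDS = {
    "drug.ka": (0.05, 10.0),            # 1/h
    "drug.Vmax_li": (0.5, 2000.0),      # µmol/h per L liver
    "drug.f_ki_Vmax": (0.05, 5000.0),   # dimensionless
    "drug.k_DAPEX_ki": (1e-4, 5.0),     # 1/h
    "drug.k_D3GEX_ki": (0.05, 100.0),   # 1/h
}

#: Bounds for the PD stage (PK parameters held fixed).
PD_STAGE_BOUNDS = {
    "pd.RTG0": (4.0, 14.0),             # mM
    "pd.Imax": (0.05, 1.0),
    "pd.IC50": (0.2, 500.0),            # ng/mL
}


@dataclass
class StudyDataset:
    """Study-format data for weighted fitting.

    ``frame`` columns: ``scenario_id, observable, time_h, mean, sd, n``;
    one row per time point. ``scenarios`` maps scenario_id to the
    Scenario under which the data were (or are assumed to have been)
    collected. Missing/non-positive SDs fall back to the median positive
    SD of their time course when weights are formed.
    """

    frame: pd.DataFrame
    scenarios: dict[str, Scenario]

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        required = {"scenario_id", "observable", "time_h", "mean", "sd", "n"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"dataset frame is missing columns {sorted(missing)}")
        if (self.frame["n"] < 1).any():
            raise ValueError("group sizes n must be >= 1")
        if (self.frame["time_h"] < 0).any():
            raise ValueError("time points must be non-negative")
        unknown = set(self.frame["scenario_id"]) - set(self.scenarios)
        if unknown:
            raise ValueError(f"frame references unknown scenarios {sorted(unknown)}")

    def weights(self) -> np.ndarray:
        """Per-point weights n_k / sigma_{i,k} with the median-SD fallback."""
        w = np.empty(len(self.frame))
        for _, group in self.frame.groupby(["scenario_id", "observable"], sort=False):
            sd = group["sd"].to_numpy(dtype=float)
            ok = np.isfinite(sd) & (sd > 0)
            fallback = float(np.median(sd[ok])) if ok.any() else 1.0
            sd = np.where(ok, sd, fallback)
            w[group.index.to_numpy()] = group["n"].to_numpy(dtype=float) / sd
        return w


@dataclass(frozen=True)
class ParameterSpace:
    """Named scalar parameters (scenario paths) with finite bounds.

    Optimization happens on log10-transformed values, so bounds must be
    positive.
    """

    names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lower) == len(self.upper)):
            raise ValueError("names and bounds must have equal lengths")
        for lo, hi in zip(self.lower, self.upper):
            if not (0 < lo < hi < np.inf):
                raise ValueError("bounds must satisfy 0 < lower < upper < inf")

    @classmethod
    def from_bounds(cls, bounds: dict[str, tuple[float, float]]) -> "ParameterSpace":
        names = tuple(bounds)
        return cls(names, tuple(bounds[k][0] for k in names),
                   tuple(bounds[k][1] for k in names))

    def apply(self, scenario: Scenario, values) -> Scenario:
        for name, v in zip(self.names, values):
            scenario = _with_param(scenario, name, float(v))
        return scenario

    def sample(self, n_starts: int, rng: np.random.Generator) -> np.ndarray:
        """Log-uniform starting points within bounds, shape (n_starts, d)."""
        lo = np.log10(self.lower)
        hi = np.log10(self.upper)
        return 10 ** rng.uniform(lo, hi, size=(n_starts, len(self.names)))


def _predict_scenario(scenario: Scenario, group: pd.DataFrame) -> dict[int, float]:
    """Simulate one scenario on its data grid; map frame index -> prediction."""
    times = np.unique(group["time_h"].to_numpy(dtype=float))
    grid = np.unique(np.concatenate([[0.0], times]))
    t_end = max(scenario.t_end, float(grid[-1]))
    sc = replace(scenario, output_grid=tuple(grid), t_end=t_end)
    tc = simulate(sc, rtol=FIT_RTOL, atol=FIT_ATOL)
    out: dict[int, float] = {}
    for obs, obs_group in group.groupby("observable", sort=False):
        if obs == "uge":
            series = tc["uge"]
        else:
            series = tc[obs]
        values = np.interp(obs_group["time_h"].to_numpy(dtype=float), tc.time, series)
        for idx, v in zip(obs_group.index.to_numpy(), values):
            out[idx] = float(v)
    return out


def residuals(values, data: StudyDataset, space: ParameterSpace) -> np.ndarray:
    """Raw residuals (prediction - observed mean), aligned with data.frame."""
    pred = np.empty(len(data.frame))
    for sid, group in data.frame.groupby("scenario_id", sort=False):
        scenario = space.apply(data.scenarios[sid], values)
        for idx, v in _predict_scenario(scenario, group).items():
            pred[idx] = v
    return pred - data.frame["mean"].to_numpy(dtype=float)


def cost(values, data: StudyDataset, space: ParameterSpace) -> float:
    """Weighted least-squares objective F = 1/2 * sum w * r^2.

    Simulation failures yield a large-but-finite penalty (logged), so
    multistart runs survive pathological start points.
    """
    try:
        r = residuals(values, data, space)
    except Exception as exc:  # noqa: BLE001 - penalty path must be broad
        logger.warning("simulation failed at %s: %s", list(values), exc)
        return PENALTY_COST
    return float(0.5 * np.sum(data.weights() * r ** 2))


@dataclass
class FitResult:
    """Best multistart run plus per-run bookkeeping."""

    parameters: dict[str, float]
    cost: float
    run_costs: list[float]
    space: ParameterSpace
    seed: int | None
    n_starts: int
    stage: str
    gof: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def values(self) -> np.ndarray:
        return np.array([self.parameters[k] for k in self.space.names])


def _stage_space(stage: str, bounds=None) -> ParameterSpace:
    if bounds is not None:
        return ParameterSpace.from_bounds(dict(bounds))
    if stage.upper() == "PK":
        return ParameterSpace.from_bounds(PK_STAGE_BOUNDS)
    if stage.upper() == "PD":
        return ParameterSpace.from_bounds(PD_STAGE_BOUNDS)
    raise ValueError(f"unknown stage {stage!r}; expected 'PK' or 'PD'")


def multistart_fit(data: StudyDataset, bounds=None, n_starts: int = 100,
                   stage: str = "PK", seed: int | None = None,
                   **least_squares_kwargs) -> FitResult:
    """Bounded local least-squares from ``n_starts`` log-uniform starts.

    Each run minimizes the weighted residual vector sqrt(w)*r on log10
    parameters with scipy's trust-region reflective solver; the best run
    (lowest F) is returned together with all run costs. Identical seeds
    give identical results.
    """
    space = _stage_space(stage, bounds)
    rng = np.random.default_rng(seed)
    starts = space.sample(n_starts, rng)
    sqrt_w = np.sqrt(data.weights())
    log_lo = np.log10(space.lower)
    log_hi = np.log10(space.upper)

    def weighted_residuals(theta: np.ndarray) -> np.ndarray:
        try:
            return sqrt_w * residuals(10 ** theta, data, space)
        except Exception as exc:  # noqa: BLE001
            logger.warning("simulation failed at %s: %s", list(10 ** theta), exc)
            return np.full(len(data.frame), np.sqrt(2 * PENALTY_COST / len(data.frame)))

    # Finite-difference steps must stay above the ODE solver's noise
    # floor, or the Jacobian degenerates into integration noise.
    least_squares_kwargs.setdefault("diff_step", 1e-3)

    run_costs: list[float] = []
    failures: list[str] = []
    best = None
    for start in starts:
        try:
            res = least_squares(
                weighted_residuals, np.log10(start), bounds=(log_lo, log_hi),
                method="trf", **least_squares_kwargs)
        except Exception as exc:  # noqa: BLE001
            failures.append(str(exc))
            run_costs.append(np.inf)
            continue
        run_costs.append(float(res.cost))
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(
            f"all {n_starts} optimization starts failed: {failures[:3]} ...")

    values = 10 ** best.x
    parameters = {name: float(v) for name, v in zip(space.names, values)}
    fit = FitResult(parameters=parameters, cost=float(best.cost),
                    run_costs=run_costs, space=space, seed=seed,
                    n_starts=n_starts, stage=stage.upper())
    fit.gof = goodness_of_fit(fit, data)
    return fit


def goodness_of_fit(fit: FitResult | dict, data: StudyDataset,
                    space: ParameterSpace | None = None) -> pd.DataFrame:
    """Per-timecourse R² and RMSE at the fitted parameters, plus a total row.

    R² is NaN (flagged in the ``note`` column) for observation series
    with zero variance, where it is undefined.
    """
    if isinstance(fit, FitResult):
        space = fit.space
        values = fit.values
    else:
        if space is None:
            raise ValueError("space must be given when fit is a plain mapping")
        values = np.array([fit[k] for k in space.names])
    r = residuals(values, data, space)
    rows = []
    for (sid, obs), group in data.frame.groupby(["scenario_id", "observable"], sort=False):
        idx = group.index.to_numpy()
        obs_mean = group["mean"].to_numpy(dtype=float)
        ssr = float(np.sum(r[idx] ** 2))
        sst = float(np.sum((obs_mean - obs_mean.mean()) ** 2))
        r2 = 1.0 - ssr / sst if sst > 0 else float("nan")
        rows.append({"scenario_id": sid, "observable": obs,
                     "r2": r2, "rmse": float(np.sqrt(ssr / len(idx))),
                     "n_points": len(idx),
                     "note": "" if sst > 0 else "zero-variance observations"})
    rows.append({"scenario_id": "__all__", "observable": "__all__",
                 "r2": float("nan"),
                 "rmse": float(np.sqrt(np.mean(r ** 2))),
                 "n_points": len(r), "note": "aggregate"})
    return pd.DataFrame(rows)
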