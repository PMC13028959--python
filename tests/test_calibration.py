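"""Weighted least-squares cost, multistart estimation, goodness of fit."""

import numpy as np
import pandas as pd
import pytest

from dapasim.calibration import (ParameterSpace, StudyDataset, cost,
                                 goodness_of_fit, multistart_fit, residuals)
from dapasim.fixtures import (RECOVERY_TRUTH_DRUG, RECOVERY_TRUTH_PD,
                              canonical_specs, generate_study)

ZERO_CV = {k: 0.0 for k in ("dap_plasma", "d3g_plasma", "dap_urine",
                            "d3g_urine", "uge")}


def _toy_dataset(scenario, mean, sd, n, time_h=4.0, observable="dap_plasma"):
    frame = pd.DataFrame([{
        "scenario_id": "s", "observable": observable, "time_h": time_h,
        "mean": mean, "sd": sd, "n": n,
    }])
    return StudyDataset(frame=frame, scenarios={"s": scenario})


@pytest.fixture(scope="module")
def small_dataset():
    """Noiseless two-arm subset for fast cost-surface checks."""
    spec = canonical_specs(RECOVERY_TRUTH_DRUG, RECOVERY_TRUTH_PD, cv=ZERO_CV)
    spec = spec["dose_ranging"]
    keep = {"dose_10mg", "dose_100mg"}
    frame = None
    ds = generate_study(spec)
    frame = ds.frame[ds.frame.scenario_id.isin(keep)].reset_index(drop=True)
    return StudyDataset(frame=frame,
                        scenarios={k: ds.scenarios[k] for k in keep})


@pytest.fixture(scope="module")
def pk_space():
    return ParameterSpace.from_bounds({
        "drug.ka": (0.05, 10.0),
        "drug.Vmax_li": (0.5, 2000.0),
    })


class TestCost:
    def test_single_point_formula(self, oral_10mg):
        """One residual with n=10, sigma=2, r=1 gives F = 0.5*(10/2)*1 = 2.5.

        The observation is placed exactly one unit below the model
        prediction (obtained through the same fitting path), so the
        residual is exactly 1 and the cost is exact.
        """
        space = ParameterSpace.from_bounds({"drug.ka": (0.05, 10.0)})
        probe = _toy_dataset(oral_10mg, mean=0.0, sd=2.0, n=10)
        prediction = float(residuals([oral_10mg.drug.ka], probe, space)[0])
        ds = _toy_dataset(oral_10mg, mean=prediction - 1.0, sd=2.0, n=10)
        F = cost([oral_10mg.drug.ka], ds, space)
        assert F == pytest.approx(2.5, abs=1e-9)

    def test_perfect_prediction_near_zero_cost(self, small_dataset, pk_space):
        # only integration noise remains (data generated at reporting
        # tolerances, fitted at the faster fitting tolerances)
        values = [RECOVERY_TRUTH_DRUG.ka, RECOVERY_TRUTH_DRUG.Vmax_li]
        assert cost(values, small_dataset, pk_space) < 1e-4

    def test_weights_linear_in_group_size(self, oral_10mg):
        space = ParameterSpace.from_bounds({"drug.ka": (0.05, 10.0)})
        f = {}
        for n in (10, 20):
            ds = _toy_dataset(oral_10mg, mean=0.0, sd=2.0, n=n)
            f[n] = cost([oral_10mg.drug.ka], ds, space)
        assert f[20] == pytest.approx(2 * f[10], rel=1e-9)

    def test_invariant_to_point_permutation(self, small_dataset, pk_space):
        values = [1.3, 40.0]
        shuffled = StudyDataset(
            frame=small_dataset.frame.sample(frac=1.0, random_state=7),
            scenarios=small_dataset.scenarios)
        assert cost(values, shuffled, pk_space) == pytest.approx(
            cost(values, small_dataset, pk_space), rel=1e-9)

    def test_moving_one_prediction_toward_observation_reduces_cost(
            self, small_dataset, pk_space):
        truth = [RECOVERY_TRUTH_DRUG.ka, RECOVERY_TRUTH_DRUG.Vmax_li]
        off = [RECOVERY_TRUTH_DRUG.ka * 1.5, RECOVERY_TRUTH_DRUG.Vmax_li]
        near = [RECOVERY_TRUTH_DRUG.ka * 1.1, RECOVERY_TRUTH_DRUG.Vmax_li]
        assert cost(near, small_dataset, pk_space) < cost(off, small_dataset,
                                                          pk_space)

    def test_missing_sd_uses_timecourse_median(self, oral_10mg):
        from dapasim.simulate import simulate
        tc = simulate(oral_10mg)
        rows = []
        for t, sd in ((2.0, 4.0), (4.0, float("nan")), (8.0, 2.0)):
            rows.append({"scenario_id": "s", "observable": "dap_plasma",
                         "time_h": t, "mean": 1.0, "sd": sd, "n": 6})
        ds = StudyDataset(frame=pd.DataFrame(rows),
                          scenarios={"s": oral_10mg})
        w = ds.weights()
        assert w[1] == pytest.approx(6.0 / 3.0)  # median of {4, 2} = 3

    def test_dataset_validation(self, oral_10mg):
        bad = pd.DataFrame([{"scenario_id": "s", "observable": "dap_plasma",
                             "time_h": 1.0, "mean": 1.0, "sd": 1.0, "n": 0}])
        with pytest.raises(ValueError, match="n must be"):
            StudyDataset(frame=bad, scenarios={"s": oral_10mg})
        with pytest.raises(ValueError, match="unknown scenarios"):
            StudyDataset(frame=bad.assign(n=5), scenarios={})


class TestGoodnessOfFit:
    def test_perfect_fit(self, small_dataset, pk_space):
        gof = goodness_of_fit({"drug.ka": RECOVERY_TRUTH_DRUG.ka,
                               "drug.Vmax_li": RECOVERY_TRUTH_DRUG.Vmax_li},
                              small_dataset, pk_space)
        per_tc = gof[gof.scenario_id != "__all__"]
        assert np.allclose(per_tc.r2, 1.0, atol=1e-6)
        assert np.allclose(per_tc.rmse, 0.0, atol=1e-3)

    def test_hand_computed_three_point_example(self, oral_10mg):
        """R^2 from the closed form 1 - SSR/SST on a 3-point series."""
        from dapasim.simulate import simulate
        tc = simulate(oral_10mg)
        times = np.array([2.0, 4.0, 8.0])
        pred = np.interp(times, tc.time, tc["dap_plasma"])
        obs = pred + np.array([1.0, -1.0, 0.5])
        frame = pd.DataFrame({
            "scenario_id": "s", "observable": "dap_plasma", "time_h": times,
            "mean": obs, "sd": 1.0, "n": 5})
        ds = StudyDataset(frame=frame, scenarios={"s": oral_10mg})
        space = ParameterSpace.from_bounds({"drug.ka": (0.05, 10.0)})
        gof = goodness_of_fit({"drug.ka": oral_10mg.drug.ka}, ds, space)
        row = gof[gof.scenario_id == "s"].iloc[0]
        ssr = 1.0 + 1.0 + 0.25
        sst = float(np.sum((obs - obs.mean()) ** 2))
        assert row.r2 == pytest.approx(1 - ssr / sst, rel=1e-4)
        assert row.rmse == pytest.approx(np.sqrt(ssr / 3), rel=1e-4)

    def test_zero_variance_series_flagged(self, oral_10mg):
        frame = pd.DataFrame({
            "scenario_id": "s", "observable": "dap_plasma",
            "time_h": [2.0, 4.0], "mean": [5.0, 5.0], "sd": 1.0, "n": 5})
        ds = StudyDataset(frame=frame, scenarios={"s": oral_10mg})
        space = ParameterSpace.from_bounds({"drug.ka": (0.05, 10.0)})
        gof = goodness_of_fit({"drug.ka": 1.0}, ds, space)
        row = gof[gof.scenario_id == "s"].iloc[0]
        assert np.isnan(row.r2) and "zero-variance" in row.note


class TestMultistart:
    def test_seeded_determinism(self, small_dataset):
        bounds = {"drug.ka": (0.2, 5.0), "drug.Vmax_li": (5.0, 200.0)}
        fit_a = multistart_fit(small_dataset, bounds=bounds, n_starts=2,
                               stage="PK", seed=42, max_nfev=8)
        fit_b = multistart_fit(small_dataset, bounds=bounds, n_starts=2,
                               stage="PK", seed=42, max_nfev=8)
        assert fit_a.parameters == fit_b.parameters
        assert fit_a.run_costs == fit_b.run_costs
        assert fit_a.cost == min(fit_a.run_costs)

    def test_two_parameter_recovery(self, small_dataset):
        bounds = {"drug.ka": (0.2, 5.0), "drug.Vmax_li": (5.0, 200.0)}
        fit = multistart_fit(small_dataset, bounds=bounds, n_starts=3,
                             stage="PK", seed=3)
        assert fit.parameters["drug.ka"] == pytest.approx(
            RECOVERY_TRUTH_DRUG.ka, rel=0.01)
        assert fit.parameters["drug.Vmax_li"] == pytest.approx(
            RECOVERY_TRUTH_DRUG.Vmax_li, rel=0.01)

    def test_unknown_stage_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="stage"):
            multistart_fit(small_dataset, stage="PKPD", n_starts=1, seed=0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            ParameterSpace.from_bounds({"drug.ka": (0.0, 1.0)})
        with pytest.raises(ValueError, match="bounds"):
            ParameterSpace.from_bounds({"drug.ka": (2.0, 1.0)})
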