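"""Scenario execution: events, determinism, scans, study emulation."""

from dataclasses import replace

import numpy as np
import pytest

from dapasim import nca
from dapasim.pbpk import mass_balance
from dapasim.reference import reference_scenario
from dapasim.simulate import (DoseEvent, Scenario, parameter_scan, run_study,
                              simulate, _get_param, _with_param)


class TestDoseEvents:
    def test_invalid_events_rejected(self):
        with pytest.raises(ValueError, match="amount"):
            DoseEvent(0.0, "oral", -5.0)
        with pytest.raises(ValueError, match="route"):
            DoseEvent(0.0, "sublingual", 5.0)

    def test_unsorted_doses_rejected(self, oral_10mg):
        with pytest.raises(ValueError, match="sorted"):
            replace(oral_10mg, doses=(DoseEvent(24.0, "oral", 10.0),
                                      DoseEvent(0.0, "oral", 10.0)))

    def test_event_atomicity_multidose(self, oral_10mg):
        """Total administered mass equals the sum of event amounts
        regardless of grid resolution."""
        doses = tuple(DoseEvent(24.0 * i, "oral", 10.0) for i in range(3))
        for dt in (0.5, 0.1):
            grid = tuple(np.arange(0.0, 96.0 + 1e-9, dt))
            sc = replace(oral_10mg, doses=doses, t_end=96.0, output_grid=grid)
            tc = simulate(sc)
            assert tc.dose_umol[-1] == pytest.approx(3 * 10.0 / 408.87 * 1000)
            assert mass_balance(tc) < 1e-6


class TestSimulate:
    def test_empty_dose_list_all_zero(self, oral_10mg):
        tc = simulate(replace(oral_10mg, doses=(), t_end=24.0))
        for q in ("dap_plasma", "d3g_plasma", "dap_urine", "d3g_urine",
                  "dap_feces", "uge"):
            assert np.all(tc[q] == 0.0)
        assert np.all(tc["rtg"] == oral_10mg.pd.RTG0)

    def test_peak_concentration_within_three_hours(self, oral_10mg):
        pk = nca.pk_summary(simulate(oral_10mg), "dap_plasma")
        assert 2.0 <= pk.tmax <= 4.0

    def test_deterministic_repeat_runs(self, oral_10mg):
        a, b = simulate(oral_10mg), simulate(oral_10mg)
        for q in a.quantities:
            assert np.array_equal(a[q], b[q])

    def test_cumulative_series_non_decreasing(self, oral_10mg):
        tc = simulate(oral_10mg)
        for q in ("dap_urine", "d3g_urine", "dap_feces", "uge"):
            assert np.all(np.diff(tc[q]) >= -1e-12)

    def test_superposition_at_subsaturating_doses(self, oral_10mg):
        """Two 10 mg doses 24 h apart must superpose shifted single-dose
        profiles within 2% (linearity far below Km)."""
        sc_two = replace(oral_10mg, doses=(DoseEvent(0.0, "oral", 10.0),
                                           DoseEvent(24.0, "oral", 10.0)),
                         t_end=72.0)
        sc_one = replace(oral_10mg, t_end=72.0)
        tc2, tc1 = simulate(sc_two), simulate(sc_one)
        shifted = np.interp(tc2.time - 24.0, tc1.time, tc1["dap_plasma"],
                            left=0.0)
        expected = np.interp(tc2.time, tc1.time, tc1["dap_plasma"]) + shifted
        second = tc2.time >= 24.0
        err = np.max(np.abs(tc2["dap_plasma"][second] - expected[second]))
        assert err / expected.max() < 0.02

    def test_tolerance_refinement_invariance(self, oral_10mg):
        """Halving solver tolerances must leave Cmax and AUC within 0.1%."""
        tc = simulate(oral_10mg, rtol=1e-8, atol=1e-10)
        tc_fine = simulate(oral_10mg, rtol=5e-9, atol=5e-11)
        pk = nca.pk_summary(tc, "dap_plasma")
        pk_fine = nca.pk_summary(tc_fine, "dap_plasma")
        assert pk.cmax == pytest.approx(pk_fine.cmax, rel=1e-3)
        assert pk.auc_0_t == pytest.approx(pk_fine.auc_0_t, rel=1e-3)

    def test_multidose_approaches_steady_state(self, oral_10mg):
        """Seven daily doses (>5 half-lives): trough 7 within 2% of trough 6."""
        doses = tuple(DoseEvent(24.0 * i, "oral", 10.0) for i in range(7))
        sc = replace(oral_10mg, doses=doses, t_end=192.0,
                     output_grid=tuple(np.arange(0.0, 192.1, 0.25)))
        tc = simulate(sc)
        c = tc["dap_plasma"]
        trough = lambda day: c[np.searchsorted(tc.time, 24.0 * day) - 1]
        assert trough(7) == pytest.approx(trough(6), rel=0.02)


class TestParameterPaths:
    def test_roundtrip_get_set(self, oral_10mg):
        sc = _with_param(oral_10mg, "drug.ka", 2.0)
        assert _get_param(sc, "drug.ka") == 2.0
        sc = _with_param(oral_10mg, "dose_mg", 25.0)
        assert all(d.amount == 25.0 for d in sc.doses)

    def test_unknown_path_rejected(self, oral_10mg):
        for path in ("drug.nope", "banana.ka", "physiology"):
            with pytest.raises(ValueError, match="unknown parameter path"):
                _with_param(oral_10mg, path, 1.0)


class TestParameterScan:
    def test_dose_scan_monotone_exposure_stable_half_life(self, oral_10mg):
        res = parameter_scan(replace(oral_10mg, t_end=96.0), "dose_mg",
                             [2.5, 10.0, 50.0, 250.0, 500.0])
        aucs = [r.pk.auc_inf for r in res]
        assert all(np.diff(aucs) > 0)
        thalfs = np.array([r.pk.thalf for r in res])
        assert np.ptp(thalfs) / thalfs.mean() < 0.05

    def test_absorption_scan_shapes_peak_not_exposure(self, oral_10mg):
        res = parameter_scan(replace(oral_10mg, t_end=168.0),
                             "physiology.f_absorption",
                             [0.1, 0.3, 1.0, 3.0, 10.0])
        cmaxs = [r.pk.cmax for r in res]
        assert all(np.diff(cmaxs) > 0)
        aucs = np.array([r.pk.auc_inf for r in res])
        assert aucs.max() / aucs.min() - 1.0 < 0.05

    def test_renal_scan_metabolite_accumulates(self, oral_10mg):
        res = parameter_scan(replace(oral_10mg, t_end=168.0),
                             "physiology.f_renal", [1.0, 0.69, 0.32, 0.19])
        d3g_auc = [nca.pk_summary(r.timecourse, "d3g_plasma").auc_inf
                   for r in res]
        assert all(np.diff(d3g_auc) > 0)  # worsening function, rising exposure


class TestRunStudy:
    def test_fed_fasted_two_arm(self):
        config = {"arms": [
            {"label": "fasted", "prandial": "fasted",
             "doses": [{"amount_mg": 10.0}], "t_end_h": 48.0},
            {"label": "fed", "prandial": "fed",
             "doses": [{"amount_mg": 10.0}], "t_end_h": 48.0},
        ]}
        arms = run_study(config)
        pk_fasted = nca.pk_summary(arms["fasted"], "dap_plasma")
        pk_fed = nca.pk_summary(arms["fed"], "dap_plasma")
        assert pk_fed.cmax < pk_fasted.cmax
        assert pk_fed.tmax > pk_fasted.tmax

    def test_renal_four_arm_uge_ordering(self):
        from dapasim.pharmacodynamics import cumulative_uge
        from dapasim.io import scenario_from_config
        arms_cfg = [{"label": c, "renal_class": c, "population": "T2DM",
                     "doses": [{"amount_mg": 10.0}], "t_end_h": 48.0}
                    for c in ("normal", "mild", "moderate", "severe")]
        arms = run_study({"arms": arms_cfg})
        uge = []
        for cfg in arms_cfg:
            sc = scenario_from_config(cfg)
            uge.append(cumulative_uge(arms[cfg["label"]], sc.physiology,
                                      sc.pd, 24.0))
        assert all(np.diff(uge) < 0)  # worsening renal function, less UGE

    def test_single_arm_matches_plain_simulate(self):
        config = {"arms": [{"label": "a", "doses": [{"amount_mg": 10.0}],
                            "t_end_h": 48.0}]}
        tc = run_study(config)["a"]
        ref = simulate(reference_scenario(dose_mg=10.0, t_end=48.0))
        assert np.array_equal(tc["dap_plasma"], ref["dap_plasma"])

    def test_malformed_arm_names_offender(self):
        config = {"arms": [{"label": "bad", "doses": [{"amount_mg": -4}]}]}
        with pytest.raises(ValueError, match="bad"):
            run_study(config)

    def test_missing_arms_rejected(self):
        with pytest.raises(ValueError, match="arms"):
            run_study({})
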