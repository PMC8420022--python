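"""Energy-expenditure decomposition: Weir equation, windows, AUC contrasts,
mouse summaries and group statistics."""

import numpy as np
import pandas as pd
import pytest

from metaphen import calorimetry as cal
from metaphen import synthetic_data as syn
from metaphen.exceptions import (DataError, DegenerateInputError, PeriodError)

from conftest import make_human_trace


class TestWeir:
    @pytest.mark.parametrize("vo2, vco2, expected", [
        (0.0, 0.0, 0.0),
        (1.0, 0.0, 1.44 * 3.94),
        (0.0, 1.0, 1.44 * 1.11),
        (250.0, 200.0, 1.44 * (3.94 * 250 + 1.11 * 200)),  # = 1738.08
    ])
    def test_direct_evaluation(self, vo2, vco2, expected):
        assert cal.weir_ee(vo2, vco2) == pytest.approx(expected, rel=1e-12)

    def test_linearity_and_vectorization(self):
        vo2 = np.array([10.0, 200.0, 315.5])
        vco2 = np.array([8.0, 170.0, 280.0])
        np.testing.assert_allclose(cal.weir_ee(3.0 * vo2, 3.0 * vco2),
                                   3.0 * cal.weir_ee(vo2, vco2), rtol=1e-12)
        # mean of EE equals EE of means (linearity used throughout)
        assert np.mean(cal.weir_ee(vo2, vco2)) == pytest.approx(
            cal.weir_ee(vo2.mean(), vco2.mean()), rel=1e-10)

    def test_negative_input_rejected(self):
        with pytest.raises(DataError):
            cal.weir_ee(-1.0, 0.0)

    def test_rer(self):
        assert cal.rer(1.0, 1.0) == 1.0
        assert cal.rer(0.8, 1.0) == pytest.approx(0.8)
        with pytest.raises(DegenerateInputError):
            cal.rer(1.0, 0.0)


class TestSteadyStateWindow:
    def test_sample_count_after_buffer(self):
        # 30-min period at 15-s sampling: 120 samples, 100 survive the 5-min buffer
        tr = make_human_trace(dur=1800.0, dt=15.0)
        win = cal.apply_steady_state_window(tr, "rest")
        assert win.time.size == 100
        assert (tr.period_labels == "rest").sum() == 120

    def test_boundary_sample_retained(self):
        tr = make_human_trace(dur=1800.0, dt=15.0)
        win = cal.apply_steady_state_window(tr, "rest")
        assert win.time.min() == 300.0

    def test_short_period_errors(self):
        t = np.arange(0.0, 240.0, 15.0)
        tr = cal.GasExchangeTrace("S", "human", t, np.ones_like(t),
                                  np.ones_like(t),
                                  np.full(t.size, "rest", dtype=object))
        with pytest.raises(PeriodError, match="rest"):
            cal.apply_steady_state_window(tr, "rest")

    def test_missing_period_errors(self, flat_trace):
        with pytest.raises(PeriodError, match="sleep"):
            cal.apply_steady_state_window(flat_trace, "sleep")


class TestRestingSummary:
    def test_constant_trace(self):
        tr = make_human_trace(ree=1500.0, rer=0.9)
        ree, r = cal.resting_summary(tr)
        assert ree == pytest.approx(1500.0, rel=1e-10)
        assert r == pytest.approx(0.9, rel=1e-10)

    def test_linear_drift_gives_midpoint(self):
        # time-weighted mean of a linear EE drift = value at the window midpoint
        t = np.arange(0.0, 1800.0, 15.0)
        vo2 = 200.0 + 0.01 * t
        tr = cal.GasExchangeTrace("S", "human", t, vo2, 0.85 * vo2,
                                  np.full(t.size, "rest", dtype=object))
        ree, _ = cal.resting_summary(tr)
        mid = 0.5 * (300.0 + t[-1])
        assert ree == pytest.approx(cal.weir_ee(200.0 + 0.01 * mid,
                                                0.85 * (200.0 + 0.01 * mid)),
                                    rel=1e-10)

    def test_zero_noise_cohort_matches_truth(self, small_cohort):
        subjects, traces = small_cohort
        for (_, row), tr in zip(subjects.iterrows(), traces):
            ree, _ = cal.resting_summary(tr)
            assert ree == pytest.approx(row.true_ree, rel=1e-9)


class TestPeriodAuc:
    def test_constant_closed_form(self):
        # constant 1440 kcal/day for a 25-min window integrates to 25
        tr = make_human_trace(ree=1440.0, dur=1800.0, dt=15.0)
        auc = cal.period_auc(tr, "rest")
        win_minutes = (1785.0 - 300.0) / 60.0
        assert auc == pytest.approx(1440.0 * win_minutes / 1440.0, rel=1e-10)

    def test_incremental_constant_baseline_zero(self):
        tr = make_human_trace(ree=1440.0)
        assert cal.period_auc(tr, "rest", mode="incremental",
                              baseline=1440.0) == pytest.approx(0.0, abs=1e-9)

    def test_trapezoid_matches_dense_grid_oracle(self):
        # piecewise-linear EE: trapezoid on coarse knots equals the dense
        # integral to <=1e-9 relative
        rng = np.random.default_rng(3)
        knots = np.arange(0.0, 1800.0 + 1e-9, 15.0)
        vals = rng.uniform(1000.0, 2000.0, knots.size)
        tr = cal.GasExchangeTrace("S", "human", knots, vals, 0.85 * vals,
                                  np.full(knots.size, "rest", dtype=object))
        auc = cal.period_auc(tr, "rest")
        dense_t = np.linspace(300.0, knots[-1], 200001)
        dense_v = np.interp(dense_t, knots, vals)
        oracle = np.trapezoid(cal.weir_ee(dense_v, 0.85 * dense_v),
                              dense_t / 60.0) / 1440.0
        assert auc == pytest.approx(oracle, rel=1e-9)

    def test_too_few_samples_errors(self):
        t = np.array([0.0, 400.0])
        tr = cal.GasExchangeTrace("S", "human", t, np.ones(2), np.ones(2),
                                  np.full(2, "rest", dtype=object))
        with pytest.raises(DegenerateInputError):
            cal.period_auc(tr, "rest")


class TestAucContrasts:
    def test_identical_periods_give_zero(self, flat_trace):
        assert cal.cognitive_ee(flat_trace) == pytest.approx(0.0, abs=1e-12)
        assert cal.thermic_effect(flat_trace) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_ten_percent_rise(self):
        tr = make_human_trace(ree=1500.0, cog_gain=0.10)
        assert cal.cognitive_ee(tr) == pytest.approx(
            0.10 * cal.period_auc(tr, "rest"), rel=1e-10)

    def test_tef_gain_recovered_exactly(self):
        tr = make_human_trace(ree=1500.0, tef_gain=0.15)
        assert cal.thermic_effect(tr) == pytest.approx(
            0.15 * cal.period_auc(tr, "rest"), rel=1e-10)

    def test_blunting_strictly_reduces_tef(self):
        cfg_kwargs = dict(n_per_group=1, noise_sd=0.0, tef_gain=0.15, seed=5)
        _, traces_full = syn.gen_ic_cohort(syn.CohortConfig(vo2_blunt=0.0,
                                                            **cfg_kwargs))
        _, traces_blunt = syn.gen_ic_cohort(syn.CohortConfig(vo2_blunt=0.5,
                                                             **cfg_kwargs))
        # trace index 4: first E4+ female (affected by the blunt)
        subjects, _ = syn.gen_ic_cohort(syn.CohortConfig(vo2_blunt=0.5,
                                                         **cfg_kwargs))
        i = subjects.index[(subjects.group == "E4+") &
                           (subjects.sex == "F")][0]
        assert cal.thermic_effect(traces_blunt[i]) < \
            cal.thermic_effect(traces_full[i])

    def test_linear_scaling_of_contrasts(self):
        tr = make_human_trace(ree=1500.0, cog_gain=0.05, tef_gain=0.12)
        scaled = cal.GasExchangeTrace(
            tr.subject_id, tr.species, tr.time, 2.0 * tr.vo2, 2.0 * tr.vco2,
            tr.period_labels)
        assert cal.thermic_effect(scaled) == pytest.approx(
            2.0 * cal.thermic_effect(tr), rel=1e-10)
        assert cal.cognitive_ee(scaled) == pytest.approx(
            2.0 * cal.cognitive_ee(tr), rel=1e-10)


class TestMouseSummaries:
    def test_zero_noise_light_mean_matches_truth(self):
        cfg = syn.MouseIcConfig(n_per_genotype={"E3": 2, "E4": 2}, seed=9)
        animals, traces = syn.gen_mouse_ic(cfg)
        for (_, row), tr in zip(animals.iterrows(), traces):
            summ = cal.mouse_cycle_summary(tr)
            light_chow = summ[(summ.cycle == "light") & (summ.diet == "chow")]
            assert light_chow.ee.iloc[0] == pytest.approx(
                row.true_ee_light_chow, rel=1e-9)
            assert light_chow.vo2.iloc[0] * 60.0 == pytest.approx(
                row.true_vo2_light_chow, rel=1e-9)

    def test_binning_matches_groupby_oracle(self):
        cfg = syn.MouseIcConfig(n_per_genotype={"E3": 1}, noise_sd=5.0,
                                sampling_minutes=10.0, seed=2)
        _, traces = syn.gen_mouse_ic(cfg)
        tr = traces[0]
        summ = cal.mouse_cycle_summary(tr, interval_s=1800.0)
        # oracle: plain two-stage pandas groupby on the same trace
        df = pd.DataFrame({
            "bin": (tr.time // 1800.0).astype(int),
            "lab": tr.period_labels,
            "ee": cal.weir_ee(tr.vo2, tr.vco2)})
        oracle = df.groupby(["lab", "bin"]).ee.mean().groupby("lab").mean()
        for _, row in summ.iterrows():
            assert row.ee == pytest.approx(
                oracle[f"{row.cycle}|{row.diet}"], rel=1e-12)

    def test_no_light_cycle_errors(self):
        t = np.arange(0.0, 3600.0, 600.0)
        tr = cal.GasExchangeTrace("M", "mouse", t, np.ones_like(t),
                                  np.ones_like(t),
                                  np.full(t.size, "dark|chow", dtype=object))
        with pytest.raises(PeriodError):
            cal.mouse_cycle_summary(tr)


class TestDietDelta:
    @staticmethod
    def _light_summaries(cfg):
        animals, traces = syn.gen_mouse_ic(cfg)
        rows_chow, rows_hcd = [], []
        for (_, a), tr in zip(animals.iterrows(), traces):
            summ = cal.mouse_cycle_summary(tr)
            light = summ[summ.cycle == "light"].set_index("diet")
            for rows, phase in ((rows_chow, "chow"), (rows_hcd, "hcd")):
                rows.append({"subject_id": a.animal_id, "genotype": a.genotype,
                             "ee": light.loc[phase, "ee"],
                             "vo2": light.loc[phase, "vo2"],
                             "vco2": light.loc[phase, "vco2"]})
        return pd.DataFrame(rows_chow), pd.DataFrame(rows_hcd)

    def test_identical_phases_null(self):
        cfg = syn.MouseIcConfig(n_per_genotype={"E3": 4},
                                hcd_vo2_gain={"E3": 0.0},
                                hcd_vco2_gain={"E3": 0.0}, seed=1)
        chow, hcd = self._light_summaries(cfg)
        deltas, tests = cal.diet_delta(chow, hcd)
        assert np.allclose(deltas[["ee", "vo2", "vco2"]].to_numpy(), 0.0)
        assert not tests.significant_increase.any()

    def test_null_vo2_gain_recovered_per_genotype(self):
        cfg = syn.MouseIcConfig(n_per_genotype={"E3": 13, "E4": 20},
                                hcd_vo2_gain={"E3": 0.10, "E4": 0.0},
                                hcd_vco2_gain={"E3": 0.12, "E4": 0.10},
                                noise_sd=2.0, seed=12)
        chow, hcd = self._light_summaries(cfg)
        _, tests = cal.diet_delta(chow, hcd)
        tests = tests.set_index(["genotype", "measure"])
        assert tests.loc[("E3", "vo2"), "significant_increase"]
        assert not tests.loc[("E4", "vo2"), "significant_increase"]
        assert tests.loc[("E4", "vco2"), "significant_increase"]

    def test_unmatched_animals_error(self):
        a = pd.DataFrame({"subject_id": ["M1"], "genotype": ["E3"], "ee": [1.0]})
        b = pd.DataFrame({"subject_id": ["M2"], "genotype": ["E3"], "ee": [1.0]})
        with pytest.raises(DataError):
            cal.diet_delta(a, b, measures=("ee",))


class TestGroupStatistics:
    def test_ancova_matches_normal_equations_oracle(self):
        # 6-point design solvable by hand via least squares
        ee = np.array([10.0, 11.0, 12.0, 9.0, 10.0, 11.0])
        mass = np.array([20.0, 22.0, 24.0, 20.0, 22.0, 24.0])
        group = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
        res = cal.mass_adjusted_group_test(ee, mass, group)
        x = np.column_stack([np.ones(6), (group == "B").astype(float), mass])
        beta = np.linalg.lstsq(x, ee, rcond=None)[0]
        assert res["adjusted_difference"] == pytest.approx(beta[1], rel=1e-9)
        assert res["mass_slope"] == pytest.approx(beta[2], rel=1e-9)

    def test_identical_groups_zero_effect(self):
        rng = np.random.default_rng(0)
        mass = np.tile(rng.uniform(20, 30, 5), 2)
        ee = 5.0 + 0.3 * mass
        group = np.repeat(["A", "B"], 5)
        res = cal.mass_adjusted_group_test(ee, mass, group)
        assert res["adjusted_difference"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_additive_effect_recovered(self):
        rng = np.random.default_rng(42)
        n = 40
        group = np.repeat(["E3", "E4"], n)
        mass = rng.normal(25.0, 2.0, 2 * n)
        ee = 10.0 + 0.2 * mass + np.where(group == "E4", -1.5, 0.0) \
            + rng.normal(0, 0.4, 2 * n)
        res = cal.mass_adjusted_group_test(ee, mass, group)
        se = (res["ci_high"] - res["ci_low"]) / (2 * 1.96)
        assert abs(res["adjusted_difference"] - (-1.5)) < 2 * se

    def test_age_regression_closed_form_and_r2(self):
        age = np.array([20.0, 25.0, 30.0, 35.0, 40.0])
        ree = 2000.0 - 5.0 * age
        res = cal.age_stratified_regression(ree, age, ["E4-"] * 5)
        st = res["strata"]["E4-"]
        slope_oracle = np.cov(age, ree, ddof=1)[0, 1] / np.var(age, ddof=1)
        assert st["slope"] == pytest.approx(slope_oracle, rel=1e-10)
        assert st["r_squared"] == pytest.approx(1.0, rel=1e-12)

    def test_slope_difference_detected(self):
        rng = np.random.default_rng(8)
        n = 60
        age_nc = rng.uniform(20, 65, n)
        age_c = rng.uniform(20, 65, n)
        ree = np.concatenate([2000 - 8.0 * age_nc + rng.normal(0, 40, n),
                              1700 + 0.0 * age_c + rng.normal(0, 40, n)])
        age = np.concatenate([age_nc, age_c])
        flag = np.repeat(["E4-", "E4+"], n)
        res = cal.age_stratified_regression(ree, age, flag)
        assert res["p_slope_difference"] < 0.01
        assert res["strata"]["E4-"]["slope"] < res["strata"]["E4+"]["slope"]

    def test_constant_age_errors(self):
        with pytest.raises(DegenerateInputError):
            cal.age_stratified_regression([1.0, 2.0, 3.0],
                                          [30.0, 30.0, 30.0],
                                          ["A", "A", "A"])


def test_carrier_composition_arithmetic():
    counts = {"E2/E4": 2, "E2/E3": 10, "E3/E3": 51, "E3/E4": 28, "E4/E4": 3}
    comp = cal.carrier_composition(counts)
    assert comp == {"carriers": 33, "non_carriers": 61, "total": 94}


def test_roundtrip_io(tmp_path, small_cohort):
    subjects, traces = small_cohort
    path = tmp_path / "traces.csv"
    syn.write_ic_cohort(traces, path, species="human")
    back = cal.read_gas_exchange(path, species="human")
    assert len(back) == len(traces)
    np.testing.assert_allclose(back[0].vo2, traces[0].vo2)
    assert back[0].covariates["group"] == traces[0].covariates["group"]
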