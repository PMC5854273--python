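import numpy as np
import pytest

from pssp_surv import (
    SurvivalCurve,
    SurvivalDataset,
    concordance_index,
    cross_validate,
    d_calibration,
    fit_cox_kp,
    fraction_dead_before_median,
    generate_weibull_ph,
    one_calibration_hl,
    predict_cox_curve,
    standard_normal_truth,
    true_survival,
)
from pssp_surv.evaluation import make_folds
from tests.conftest import exact_truth_curve


def uncensored_dataset(times):
    times = np.asarray(times, dtype=float)
    return SurvivalDataset(
        np.zeros((times.size, 1)), ["x"], times, np.ones(times.size, dtype=int)
    )


def linear_curve(span):
    return SurvivalCurve(np.array([0.0, span]), np.array([1.0, 0.0]), "linear")


class TestConcordance:
    def test_perfectly_ordered_scores(self):
        ds = uncensored_dataset(np.arange(1.0, 21.0))
        assert concordance_index(-ds.time, ds) == 1.0  # higher score = earlier death

    def test_anti_ordered_scores(self):
        ds = uncensored_dataset(np.arange(1.0, 21.0))
        assert concordance_index(ds.time, ds) == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        ds = uncensored_dataset(rng.exponential(100.0, size=1000) + 1e-3)
        c = concordance_index(rng.normal(size=1000), ds)
        assert c == pytest.approx(0.5, abs=0.03)

    def test_no_comparable_pairs_rejected(self):
        ds = SurvivalDataset(np.zeros((2, 1)), ["x"], np.array([5.0, 3.0]), np.array([0, 0]))
        with pytest.raises(ValueError, match="comparable"):
            concordance_index(np.array([1.0, 2.0]), ds)


class TestOneCalibration:
    def test_statistic_zero_when_predictions_match_rates(self):
        # 100 patients, identical predicted death prob 0.3 by t=600,
        # exactly 3 deaths per block of 10 -> every decile has O = E.
        n, t = 100, 600.0
        times, events = [], []
        for _ in range(10):
            times += [100.0] * 3 + [1500.0] * 7
            events += [1] * 3 + [0] * 7
        ds = SurvivalDataset(np.zeros((n, 1)), ["x"], np.array(times), np.array(events))
        curves = [
            SurvivalCurve(np.array([0.0, 2000.0]), np.array([1.0, 0.0]), "linear")
        ] * n  # S(600) = 0.7 for everyone
        res = one_calibration_hl(curves, ds, t)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0
        assert res.dof == 8  # 10 groups - 2

    def test_true_model_calibrated_and_shifted_model_not(self):
        """Analytic curves pass the HL test at typical rates; curves with
        survival inflated by +0.15 at the horizon fail it."""
        truth = standard_normal_truth(beta=(0.6,), weibull_scale=3000.0)
        t = 1500.0
        passed_true, rejected_shifted = 0, 0
        n_seeds = 10
        for seed in range(n_seeds):
            ds = generate_weibull_ph(2000, truth, seed=500 + seed)
            true_curves, shifted = [], []
            for x, ti in zip(ds.X, ds.time):
                s_t = true_survival(truth, x, t)
                true_curves.append(exact_truth_curve(truth, x, [ti, t], 40000.0))
                shifted_probs = np.clip(np.array([1.0, s_t + 0.15, s_t + 0.15]), 0, 1)
                shifted.append(
                    SurvivalCurve(np.array([0.0, t, 40000.0]), shifted_probs, "linear")
                )
            passed_true += one_calibration_hl(true_curves, ds, t).p_value > 0.05
            rejected_shifted += one_calibration_hl(shifted, ds, t).p_value < 0.05
        assert passed_true >= 8
        assert rejected_shifted == n_seeds

    def test_patients_censored_before_horizon_are_excluded(self):
        times = np.array([100.0, 500.0, 800.0, 900.0] * 15)
        events = np.array([0, 1, 0, 1] * 15)
        ds = SurvivalDataset(np.zeros((60, 1)), ["x"], times, events)
        curves = [linear_curve(2000.0)] * 60
        res = one_calibration_hl(curves, ds, 600.0, bins=5)
        assert res.observed.sum() == 15  # only the 500-day deaths occur by t
        # the 100-day censored patients contribute to no group: 45 remain
        assert res.expected.sum() == pytest.approx(45 * 0.3)


class TestDCalibration:
    def test_uniform_deciles_give_statistic_zero(self):
        # ten deaths per decile: S(d) = 1 - d/100 hits each decile's midpoint
        deaths = np.concatenate([[100 * (1 - (b + 0.5) / 10)] * 10 for b in range(10)])
        ds = uncensored_dataset(deaths)
        curves = [linear_curve(100.0)] * 100
        res = d_calibration(curves, ds)
        assert res.statistic == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == 1.0

    def test_all_mass_in_top_decile(self):
        ds = uncensored_dataset(np.full(100, 5.0))
        curves = [linear_curve(100.0)] * 100  # S(5) = 0.95 for every death
        res = d_calibration(curves, ds)
        assert res.statistic == pytest.approx(900.0)
        assert res.p_value < 1e-100

    def test_boundary_values_bin_upward(self):
        # S(d) = 0.1 belongs to [0.1, 0.2); S(d) = 1.0 to the top bin
        flat_then_drop = SurvivalCurve(
            np.array([0.0, 10.0, 20.0]), np.array([1.0, 1.0, 0.0]), "linear"
        )
        ds = uncensored_dataset(np.array([90.0, 5.0]))
        curves = [linear_curve(100.0), flat_then_drop]
        res = d_calibration(curves, ds)
        assert res.observed[1] == 1.0  # S=0.1 from the linear curve
        assert res.observed[9] == 1.0  # S=1.0 on the flat segment

    def test_censored_mass_spreads_uniformly_and_is_conserved(self):
        times = np.array([50.0, 30.0, 75.0])
        events = np.array([1, 0, 0])
        ds = SurvivalDataset(np.zeros((3, 1)), ["x"], times, events)
        curves = [linear_curve(100.0)] * 3
        res = d_calibration(curves, ds)
        assert res.observed.sum() == pytest.approx(3.0)
        # censored at 30 -> q = 0.7: mass 1/7 in each of the 7 bins below 0.7;
        # censored at 75 -> q = 0.25: mass 0.4, 0.4, 0.2 in the bottom 3 bins
        assert res.observed[0] == pytest.approx(1 / 7 + 0.4)
        assert res.observed[2] == pytest.approx(1 / 7 + 0.2)
        # death at 50 -> S = 0.5 exactly -> one full count in bin [0.5, 0.6)
        assert res.observed[5] == pytest.approx(1.0 + 1 / 7)

    def test_probability_integral_transform_uniformity(self):
        """True-model curves on uncensored data: the statistic behaves as a
        null chi-square, passing at typical rates across seeds."""
        truth = standard_normal_truth(beta=(0.5, -0.3), weibull_scale=2500.0)
        passed = 0
        n_seeds = 10
        for seed in range(n_seeds):
            ds = generate_weibull_ph(2000, truth, seed=700 + seed)
            curves = [exact_truth_curve(truth, x, [t], 50000.0) for x, t in zip(ds.X, ds.time)]
            passed += d_calibration(curves, ds).p_value > 0.05
        assert passed >= 8

    def test_invariant_to_patient_ordering(self):
        truth = standard_normal_truth(beta=(0.5,), weibull_scale=2500.0, censor_rate=1 / 3000)
        ds = generate_weibull_ph(300, truth, seed=31)
        curves = [exact_truth_curve(truth, x, [t], 50000.0) for x, t in zip(ds.X, ds.time)]
        res = d_calibration(curves, ds)
        perm = np.random.default_rng(0).permutation(ds.n)
        res_perm = d_calibration([curves[i] for i in perm], ds.subset(perm))
        assert np.allclose(res.observed, res_perm.observed)
        assert res.statistic == pytest.approx(res_perm.statistic)


class TestFractionDeadBeforeMedian:
    def test_true_model_near_half(self):
        truth = standard_normal_truth(beta=(0.5,), weibull_scale=2500.0)
        ds = generate_weibull_ph(2000, truth, seed=41)
        curves = []
        for x, t in zip(ds.X, ds.time):
            med = truth.weibull_scale * (
                np.log(2.0) * np.exp(-truth.linear_predictor(x)[0])
            ) ** (1 / truth.weibull_shape)
            curves.append(exact_truth_curve(truth, x, [t, med], 50000.0))
        assert fraction_dead_before_median(curves, ds) == pytest.approx(0.5, abs=0.03)

    def test_overestimating_model_pushes_fraction_up(self):
        # predicted medians far beyond every death -> everyone dies "early"
        ds = uncensored_dataset(np.linspace(10.0, 100.0, 50))
        curves = [linear_curve(100000.0)] * 50
        assert fraction_dead_before_median(curves, ds) == 1.0

    def test_death_exactly_at_median_not_counted(self):
        ds = uncensored_dataset(np.array([50.0]))
        curves = [linear_curve(100.0)]  # predicted median = 50 exactly
        assert fraction_dead_before_median(curves, ds) == 0.0

    def test_curve_never_reaching_half_excluded(self, caplog):
        flat = SurvivalCurve(np.array([0.0, 100.0]), np.array([1.0, 0.8]), "linear")
        ds = uncensored_dataset(np.array([50.0, 20.0]))
        frac = fraction_dead_before_median([flat, linear_curve(100.0)], ds)
        assert frac == 1.0  # only the second patient counts (20 < 50)


class TestCrossValidation:
    @staticmethod
    def cox_fit_predict(train_ds, test_ds):
        model = fit_cox_kp(train_ds)
        return [predict_cox_curve(model, x) for x in test_ds.X]

    def test_patient_folds_partition_everyone(self):
        truth = standard_normal_truth(beta=(0.5,), weibull_scale=2500.0)
        ds = generate_weibull_ph(100, truth, seed=51)
        folds = make_folds(ds, folds=5, group_by="patient", seed=3)
        sizes = [len(f) for f in folds]
        assert sizes == [20] * 5
        assert sorted(np.concatenate(folds)) == list(range(100))

    def test_center_folds_keep_centers_disjoint(self):
        truth = standard_normal_truth(beta=(0.5,), weibull_scale=2500.0)
        ds = generate_weibull_ph(200, truth, seed=52)
        rng = np.random.default_rng(1)
        ds.center = rng.choice([f"C{i}" for i in range(12)], size=200)
        folds = make_folds(ds, folds=4, group_by="center", seed=3)
        seen = [set(ds.center[f]) for f in folds]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not (seen[i] & seen[j])

    def test_in_fold_selection_recorded_per_fold(self):
        truth = standard_normal_truth(beta=(0.8, 0.0), weibull_scale=2500.0)
        ds = generate_weibull_ph(400, truth, seed=53)
        report = cross_validate(
            ds,
            self.cox_fit_predict,
            folds=4,
            seed=5,
            eval_times=[1000.0],
            select=lambda tr: [
                n for n, b in zip(tr.variable_names, [True, False]) if b
            ],
        )
        assert len(report.fold_selections) == 4
        assert all(sel == ["x0"] for sel in report.fold_selections)
        assert 0.0 <= report.c_index <= 1.0
        assert len(report.fold_d_cal_p) == 4

    def test_deterministic_given_seed(self):
        truth = standard_normal_truth(beta=(0.5,), weibull_scale=2500.0)
        ds = generate_weibull_ph(200, truth, seed=54)
        r1 = cross_validate(ds, self.cox_fit_predict, folds=4, seed=9, eval_times=[1000.0])
        r2 = cross_validate(ds, self.cox_fit_predict, folds=4, seed=9, eval_times=[1000.0])
        assert r1.c_index == r2.c_index
        assert r1.d_cal.statistic == r2.d_cal.statistic
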