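import numpy as np
import pytest

from pssp_surv import (
    SurvivalDataset,
    TimeGrid,
    build_interval_targets,
    choose_time_grid,
    fit_pssp,
    generate_piecewise_ph,
    generate_weibull_ph,
    predict_curve,
    predict_population_km,
    standard_normal_truth,
    survival_at,
)
from pssp_surv.pssp import interval_death_probabilities, load_pssp_model, save_pssp_model
from pssp_surv.simulate import PiecewiseTruth


def uncensored(times, X=None):
    times = np.asarray(times, dtype=float)
    X = np.zeros((times.size, 1)) if X is None else np.asarray(X, dtype=float)
    return SurvivalDataset(X, [f"x{i}" for i in range(X.shape[1])], times, np.ones(times.size, dtype=int))


class TestTimeGrid:
    def test_quantile_placement_uniform_events(self):
        ds = uncensored(np.arange(1.0, 101.0))
        grid = choose_time_grid(ds, k=4)
        assert np.allclose(grid.points, [25, 50, 75, 100], atol=1.0)

    def test_k1_is_last_event_quantile(self):
        ds = uncensored(np.arange(1.0, 101.0))
        grid = choose_time_grid(ds, k=1)
        assert grid.points[0] == pytest.approx(100.0)

    def test_tied_events_collapse_grid(self, caplog):
        ds = uncensored(np.full(20, 30.0))
        grid = choose_time_grid(ds, k=3)
        assert grid.points.tolist() == [30.0]

    def test_include_merges_horizons(self):
        ds = uncensored(np.arange(1.0, 101.0))
        grid = choose_time_grid(ds, k=4, include=[33.0, 999.0])
        assert 33.0 in grid.points
        assert 999.0 not in grid.points  # beyond the last event time

    def test_invalid_k(self):
        ds = uncensored(np.arange(1.0, 11.0))
        with pytest.raises(ValueError):
            choose_time_grid(ds, k=0)


class TestIntervalTargets:
    GRID = TimeGrid(np.array([365.0, 730.0, 1825.0]))

    def label_for(self, time, event):
        ds = SurvivalDataset(np.zeros((1, 1)), ["x"], np.array([time]), np.array([event]))
        out = []
        for include, label in build_interval_targets(ds, self.GRID):
            out.append((bool(include[0]), int(label[0])))
        return out

    def test_death_inside_second_interval(self):
        assert self.label_for(500.0, 1) == [(True, 0), (True, 1), (False, 0)]

    def test_censored_inside_first_interval_excluded_everywhere(self):
        assert self.label_for(200.0, 0) == [(False, 0), (False, 0), (False, 0)]

    def test_long_survivor_all_zero_labels(self):
        assert self.label_for(2000.0, 0) == [(True, 0), (True, 0), (True, 0)]


class TestFitPSSP:
    def test_single_interval_equals_plain_logistic_regression(self):
        """With one grid point and no censoring PSSP is an ordinary
        logistic regression of death-by-t1; the unpenalized fit must match
        an independent Newton MLE to 1e-6 on the original scale."""
        sm = pytest.importorskip("statsmodels.api")
        truth = standard_normal_truth(beta=(0.7, -0.4), weibull_scale=2000.0)
        ds = generate_weibull_ph(1500, truth, seed=11)
        t1 = float(np.quantile(ds.time, 0.5))
        model = fit_pssp(ds, grid=TimeGrid(np.array([t1])), regularization=0.0)

        # de-standardize (intercept, weights) back to the raw covariate scale
        w_std = model.coefficients[0, 1:]
        w = w_std / model.standardize_scale
        b = model.coefficients[0, 0] - np.sum(w_std * model.standardize_mean / model.standardize_scale)

        y = ((ds.event == 1) & (ds.time <= t1)).astype(int)
        oracle = sm.Logit(y, sm.add_constant(ds.X)).fit(disp=0, tol=1e-12)
        assert np.allclose(np.concatenate(([b], w)), oracle.params, atol=1e-6)

    def test_interval_risk_increases_with_hazardous_covariate(self):
        truth = standard_normal_truth(beta=(0.7,), weibull_scale=3000.0, censor_admin=4000.0)
        ds = generate_weibull_ph(2000, truth, seed=5)
        model = fit_pssp(ds, k=5, regularization=0.01)
        q_hi = interval_death_probabilities(model, np.array([1.5]))
        q_lo = interval_death_probabilities(model, np.array([-1.5]))
        assert np.all(q_hi > q_lo)

    def test_ridge_limit_collapses_to_population_rates(self):
        truth = standard_normal_truth(beta=(0.7,), weibull_scale=3000.0, censor_admin=4000.0)
        ds = generate_weibull_ph(1000, truth, seed=6)
        model = fit_pssp(ds, k=4, regularization=1e7)
        assert np.max(np.abs(model.coefficients[:, 1:])) < 1e-3
        q = interval_death_probabilities(model, np.zeros(1))
        for (include, label), qj in zip(build_interval_targets(ds, model.grid), q):
            assert qj == pytest.approx(label[include].mean(), abs=0.01)

    def test_zero_event_interval_rejected(self):
        ds = uncensored(np.linspace(100.0, 200.0, 50))
        with pytest.raises(ValueError, match="interval 1"):
            fit_pssp(ds, grid=TimeGrid(np.array([50.0, 200.0])), regularization=0.1)

    def test_deterministic_and_serializable(self, tmp_path):
        truth = standard_normal_truth(beta=(0.5, -0.2), weibull_scale=2500.0)
        ds = generate_weibull_ph(600, truth, seed=9)
        m1 = fit_pssp(ds, k=4, regularization="cv")
        m2 = fit_pssp(ds, k=4, regularization="cv")
        assert np.array_equal(m1.coefficients, m2.coefficients)
        save_pssp_model(m1, tmp_path / "m.json")
        m3 = load_pssp_model(tmp_path / "m.json")
        x = ds.X[17]
        assert np.array_equal(predict_curve(m1, x).probs, predict_curve(m3, x).probs)


class TestPredictCurve:
    @pytest.fixture(scope="class")
    def fitted(self):
        truth = standard_normal_truth(beta=(0.7,), weibull_scale=3000.0, censor_admin=4000.0)
        ds = generate_weibull_ph(2000, truth, seed=5)
        return fit_pssp(ds, k=5, regularization=0.01)

    def test_monotone_with_unit_anchor(self, fitted):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = predict_curve(fitted, rng.normal(size=1))
            assert c.probs[0] == 1.0
            assert np.all(np.diff(c.probs) <= 1e-12)

    def test_identical_patients_identical_curves(self, fitted):
        x = np.array([0.3])
        assert np.array_equal(predict_curve(fitted, x).probs, predict_curve(fitted, x).probs)

    def test_higher_risk_curve_lies_below(self, fitted):
        hi = predict_curve(fitted, np.array([2.0]))
        lo = predict_curve(fitted, np.array([-2.0]))
        assert np.all(hi.probs[1:] < lo.probs[1:])

    def test_missing_covariate_rejected(self, fitted):
        with pytest.raises(ValueError, match="x0"):
            predict_curve(fitted, np.array([np.nan]))
        with pytest.raises(ValueError):
            predict_curve(fitted, np.array([1.0, 2.0]))


class TestCalibrationInTheLarge:
    def test_mean_predicted_tracks_empirical_survival(self):
        """Uncensored cohort: averaged predicted survival at each grid
        point stays within 2% of the empirical survivor fraction."""
        truth = standard_normal_truth(beta=(0.5, -0.3, 0.2), weibull_scale=3000.0)
        ds = generate_weibull_ph(2000, truth, seed=21)
        model = fit_pssp(ds, k=5, regularization=0.01)
        mean_pred = np.mean(
            [[survival_at(predict_curve(model, x), t) for t in model.grid.points] for x in ds.X],
            axis=0,
        )
        empirical = [(ds.time > t).mean() for t in model.grid.points]
        assert np.allclose(mean_pred, empirical, atol=0.02)


class TestPiecewiseParameterRecovery:
    def test_interval_coefficients_match_known_death_odds(self):
        """Piecewise-exponential truth with a binary covariate: each
        interval's fitted log-odds coefficients must land within 3 SE of
        the analytic interval death-odds parameters."""
        sm = pytest.importorskip("statsmodels.api")
        truth = PiecewiseTruth([730.0], np.log([4e-4, 2e-4]), [[0.7], [-0.5]])
        grid = TimeGrid(np.array([730.0, 2500.0]))
        widths = [730.0, 1770.0]

        seeds_ok = 0
        n_seeds = 8
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.binomial(1, 0.5, size=(5000, 1)).astype(float)
            ds = generate_piecewise_ph(5000, truth, X=X, seed=100 + seed)
            model = fit_pssp(ds, grid=grid, regularization=0.0)

            all_within = True
            for j, (lam, beta_j, width) in enumerate(zip([4e-4, 2e-4], [0.7, -0.5], widths)):
                q0 = 1 - np.exp(-lam * width)
                q1 = 1 - np.exp(-lam * np.exp(beta_j) * width)
                true_intercept = np.log(q0 / (1 - q0))
                true_coef = np.log(q1 / (1 - q1)) - true_intercept

                include, label = build_interval_targets(ds, grid)[j]
                oracle = sm.Logit(label[include], sm.add_constant(ds.X[include])).fit(disp=0)
                se = oracle.bse
                all_within &= abs(model.coefficients[j, 0] - true_intercept) < 3 * se[0]
                all_within &= abs(model.coefficients[j, 1] - true_coef) < 3 * se[1]
            seeds_ok += all_within
        # a single 3-SE excursion among 32 checks is expected occasionally
        assert seeds_ok >= n_seeds - 2


class TestPopulationKM:
    def test_hand_computed_product_limit(self, km_hand_dataset):
        curve = predict_population_km(km_hand_dataset)
        assert survival_at(curve, 10) == pytest.approx(0.75)
        assert survival_at(curve, 20) == pytest.approx(0.375)

    def test_no_censoring_reduces_to_survivor_fraction(self):
        ds = uncensored([1.0, 2.0, 3.0, 4.0, 5.0])
        curve = predict_population_km(ds)
        assert survival_at(curve, 3.0) == pytest.approx(2 / 5)

    def test_single_death_steps_to_zero(self):
        ds = uncensored([5.0])
        curve = predict_population_km(ds)
        assert survival_at(curve, 5.0) == 0.0
        assert survival_at(curve, 4.999) == 1.0

    def test_no_events_flat_with_warning(self, caplog):
        ds = SurvivalDataset(np.zeros((3, 1)), ["x"], np.array([1.0, 2.0, 3.0]), np.zeros(3, dtype=int))
        curve = predict_population_km(ds)
        assert survival_at(curve, 100.0) == 1.0
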