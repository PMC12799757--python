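"""The L1 age regressor and the three model architectures."""

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from hemaspec import (
    GenderStratifiedRegressor,
    HierarchicalAgeRegressor,
    LassoAgeRegressor,
    fit_gender,
    fit_hierarchical,
    fit_lasso,
    normalize,
    predict,
    predict_gender,
    predict_hierarchical,
)
from hemaspec.models import fit_from_dict, fit_to_dict


def _single_band_problem(rng, n=80, p=5, active=2, slope=24.0, intercept=100.0):
    """y depends exactly linearly on one band; the rest carry no signal."""
    X = rng.uniform(0.5, 1.5, size=(n, p))
    y = slope * X[:, active] + intercept
    groups = np.repeat([f"S{i}" for i in range(8)], n // 8)
    return X, y, groups


class TestLassoRegressor:
    def test_near_zero_penalty_recovers_ols_solution(self, rng):
        """In the lambda -> 0 limit the fit must match ordinary least squares."""
        X, y, groups = _single_band_problem(rng)
        fit = LassoAgeRegressor(alpha_grid=[1e-10]).fit(X, y, groups=groups)
        design = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]  # independent OLS oracle
        assert fit.intercept_ == pytest.approx(beta[0], abs=1e-6)
        assert np.allclose(fit.coef_, beta[1:], atol=1e-6)
        assert fit.coef_[2] == pytest.approx(24.0, abs=1e-6)

    def test_agrees_with_coordinate_descent_at_moderate_penalty(self, rng):
        """The LARS-path solution must match an independent solver of the
        same objective, (1/2n)*RSS + alpha*L1, on standardized features."""
        X = rng.normal(size=(60, 12))
        y = X[:, 0] * 3 - X[:, 5] + rng.normal(scale=0.3, size=60)
        alpha = 0.05
        fit = LassoAgeRegressor(alpha_grid=[alpha]).fit(X, y)
        Xs = (X - fit.center_) / fit.scale_
        cd = Lasso(alpha=alpha, max_iter=200000, tol=1e-12).fit(Xs, y)
        assert np.allclose(fit.coef_ * fit.scale_, cd.coef_, atol=1e-6)

    def test_constant_band_gets_exactly_zero_coefficient(self, rng):
        X, y, groups = _single_band_problem(rng)
        X[:, 4] = 0.7
        fit = LassoAgeRegressor(n_alphas=20).fit(X, y, groups=groups)
        assert fit.coef_[4] == 0.0
        assert 5 not in fit.selected_bands_

    def test_full_shrinkage_limit_is_the_mean_predictor(self, rng):
        X, y, groups = _single_band_problem(rng)
        fit = LassoAgeRegressor(alpha_grid=[1e6, 2e6]).fit(X, y, groups=groups)
        assert np.array_equal(fit.coef_, np.zeros(5))
        assert fit.intercept_ == pytest.approx(y.mean())
        assert fit.predict(X[:3]) == pytest.approx([y.mean()] * 3)
        assert fit.selected_bands_.size == 0

    def test_selected_band_count_nonincreasing_along_penalty_path(self, small_recordings):
        dataset = normalize(small_recordings, "divide")
        grid_alphas = np.logspace(2, -2, 12)
        counts = []
        for alpha in grid_alphas:
            fit = LassoAgeRegressor(alpha_grid=[alpha]).fit(
                dataset.X, dataset.y, groups=dataset.subject
            )
            counts.append(len(fit.selected_bands_))
        # alphas descend along the grid, so the selected-band count grows
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_fit_is_deterministic(self, small_recordings):
        dataset = normalize(small_recordings, "divide")
        a = fit_lasso(dataset, random_state=3)
        b = fit_lasso(dataset, random_state=3)
        assert a.alpha_ == b.alpha_
        assert np.array_equal(a.coef_, b.coef_)
        assert a.intercept_ == b.intercept_

    def test_constant_target_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="degenerate"):
            LassoAgeRegressor().fit(X, np.full(10, 5.0))

    def test_fold_reduction_warns_with_few_subjects(self, rng):
        X, y, _ = _single_band_problem(rng)
        groups = np.repeat(["A", "B", "C"], len(y) // 3 + 1)[: len(y)]
        with pytest.warns(UserWarning, match="reducing inner folds"):
            LassoAgeRegressor(inner_folds=5, n_alphas=10).fit(X, y, groups=groups)

    def test_predict_rejects_non_finite_input(self, rng):
        X, y, groups = _single_band_problem(rng)
        fit = LassoAgeRegressor(n_alphas=10).fit(X, y, groups=groups)
        bad = np.full((1, 5), np.nan)
        with pytest.raises(ValueError, match="finite"):
            fit.predict(bad)


def _hand_fit(intercept, band_weights, p=204):
    """A LassoAgeRegressor with hand-set coefficients (identity scaling)."""
    fit = LassoAgeRegressor()
    fit.n_features_in_ = p
    fit.center_ = np.zeros(p)
    fit.scale_ = np.ones(p)
    fit.coef_ = np.zeros(p)
    for band, w in band_weights.items():
        fit.coef_[band - 1] = w
    fit.intercept_ = intercept
    fit.alpha_ = 1.0
    fit.alpha_grid_ = np.array([1.0])
    fit.cv_mse_mean_ = None
    fit.selected_bands_ = np.flatnonzero(fit.coef_) + 1
    return fit


class TestPredict:
    def test_hand_arithmetic(self):
        fit = _hand_fit(48.0, {25: 240.0})
        x = np.zeros(204)
        x[24] = 0.5
        assert predict(fit, x) == pytest.approx(168.0)

    def test_zero_coefficients_give_intercept(self, rng):
        fit = _hand_fit(77.0, {})
        assert predict(fit, rng.normal(size=204)) == pytest.approx(77.0)


class TestHierarchical:
    @pytest.mark.parametrize(
        "gate_output, expect_branch", [(100.0, "young"), (168.0, "old"), (400.0, "old")]
    )
    def test_regression_gate_routing(self, gate_output, expect_branch):
        model = HierarchicalAgeRegressor(gate="regression")
        model.gate_ = _hand_fit(gate_output, {})
        model.young_ = _hand_fit(10.0, {})
        model.old_ = _hand_fit(300.0, {})
        model.n_features_in_ = 204
        expected = 10.0 if expect_branch == "young" else 300.0
        assert predict_hierarchical(model, np.zeros(204)) == pytest.approx(expected)

    @pytest.mark.parametrize("gate", ["logistic", "regression"])
    def test_agrees_with_branch_on_consistently_routed_samples(self, small_recordings, gate):
        dataset = normalize(small_recordings, "divide")
        model = fit_hierarchical(dataset, gate=gate, n_alphas=30)
        to_old = model.gate_decision(dataset.X)
        true_old = dataset.y > model.threshold_hours
        consistent = to_old == true_old
        assert consistent.any()
        combined = model.predict(dataset.X)
        branch = np.where(to_old, model.old_.predict(dataset.X), model.young_.predict(dataset.X))
        assert np.array_equal(combined[consistent], branch[consistent])

    def test_empty_stratum_is_named(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.uniform(0, 100, size=20)  # nobody older than 7 days
        with pytest.raises(ValueError, match="old"):
            HierarchicalAgeRegressor().fit(X, y)

    def test_day7_samples_train_both_branches(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.r_[np.full(10, 100.0), np.full(10, 168.0), np.full(10, 300.0)]
        y += rng.uniform(0, 1, 30)  # break exact-tie degeneracy in targets
        y[10:20] = 168.0
        model = HierarchicalAgeRegressor(estimator=LassoAgeRegressor(n_alphas=5))
        model.fit(X, y)
        # each branch saw its stratum plus the boundary samples
        assert model.young_ is not model.old_


class TestGender:
    def test_routes_by_sex_and_rejects_unknown_label(self, small_recordings):
        dataset = normalize(small_recordings, "divide")
        model = fit_gender(dataset, n_alphas=20)
        assert set(model.estimators_) == {"M", "F"}
        for sex in ("M", "F"):
            i = int(np.flatnonzero(dataset.sex == sex)[0])
            routed = predict_gender(model, dataset.X[i], sex)
            direct = float(model.estimators_[sex].predict(dataset.X[[i]])[0])
            assert routed == direct
        with pytest.raises(ValueError, match="sex label"):
            predict_gender(model, dataset.X[0], "X")

    def test_sex_labels_required(self, rng):
        X, y, _ = _single_band_problem(rng)
        with pytest.raises(ValueError, match="sex"):
            GenderStratifiedRegressor().fit(X, y)


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, small_recordings, tmp_path):
        dataset = normalize(small_recordings, "divide")
        fits = {
            "lasso": fit_lasso(dataset, n_alphas=20),
            "hier": fit_hierarchical(dataset, n_alphas=20),
            "gender": fit_gender(dataset, n_alphas=20),
        }
        X = dataset.X[:7]
        for name, fit in fits.items():
            back = fit_from_dict(fit_to_dict(fit))
            if name == "gender":
                a, b = fit.predict(X, sex=dataset.sex[:7]), back.predict(X, sex=dataset.sex[:7])
            else:
                a, b = fit.predict(X), back.predict(X)
            assert np.allclose(a, b, rtol=0, atol=1e-12), name
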