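import numpy as np
import pytest

from sctwiner.glm import (
    PenaltyConfig,
    WeightedLogit,
    cross_validate,
    penalized_objective,
)

from conftest import make_logistic_instance
from oracles import penalized_logistic_oracle


class TestPenaltyConfig:
    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.5])
    def test_pure_lasso_and_ridge_excluded(self, alpha):
        with pytest.raises(ValueError):
            PenaltyConfig(0.1, alpha)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            PenaltyConfig(-1.0, 0.5)

    def test_weights_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            PenaltyConfig(0.1, 0.5, np.array([0.5, 1.2]))


class TestPredictProbability:
    def _null_fit(self):
        X, y, _ = make_logistic_instance(0, weighted=False)
        m = WeightedLogit(X, y, standardize=False)
        return m.fit(1e6, 0.5)  # full shrinkage -> beta = 0

    def test_null_model_balanced_gives_half(self):
        X = np.zeros((4, 2)) + np.arange(8).reshape(4, 2)  # non-constant
        y = np.array([0, 1, 0, 1.0])
        res = WeightedLogit(X, y, standardize=False).fit(1e6, 0.5)
        # intercept = log(n1/n0) = 0 for balanced classes
        assert res.intercept == pytest.approx(0.0, abs=1e-8)
        assert res.predict_probability(np.zeros(2))[0] == pytest.approx(0.5, abs=1e-8)

    def test_closed_form_values(self):
        res = self._null_fit()
        res.coefficients[:] = 0.0
        res.intercept = np.log(3.0)
        assert res.predict_probability(np.zeros(res.model.n_features))[0] == pytest.approx(0.75)
        res.intercept = 1.0
        assert res.predict_probability(np.zeros(res.model.n_features))[0] == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        res = self._null_fit()
        with pytest.raises(ValueError, match="features"):
            res.predict_probability(np.zeros(3))

    def test_overflow_safe(self):
        res = self._null_fit()
        res.coefficients[:] = 100.0
        p = res.predict_probability(np.full(res.model.n_features, 100.0))
        assert p[0] == 1.0  # saturates without warnings/nan


class TestFit:
    def test_full_shrinkage_limit(self):
        X, y, _ = make_logistic_instance(2, weighted=False)
        res = WeightedLogit(X, y, standardize=False).fit(1e6, 0.5)
        assert res.n_selected == 0
        n1 = y.sum()
        assert res.intercept == pytest.approx(np.log(n1 / (len(y) - n1)), abs=1e-6)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).random((5, 2))
        with pytest.raises(ValueError, match="both classes"):
            WeightedLogit(X, np.ones(5))

    def test_non_finite_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            WeightedLogit(X, np.array([0, 1, 0, 1.0]))

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 4))
        X[:, 2] = 7.0
        y = (rng.random(30) < 0.5).astype(float)
        y[:2] = [0, 1]
        with pytest.warns(UserWarning, match="constant"):
            m = WeightedLogit(X, y)
        res = m.fit(0.01, 0.5)
        assert res.coefficients[2] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_generic_convex_oracle(self, seed):
        X, y, w = make_logistic_instance(seed)
        lam, alpha = 0.03, 0.5
        res = WeightedLogit(X, y, penalty_weights=w, standardize=False).fit(
            lam, alpha, tol=1e-10
        )
        _, _, obj_oracle = penalized_logistic_oracle(X, y, w, lam, alpha)
        assert res.objective == pytest.approx(obj_oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_uniform_weights_match_standard_en_solver(self, seed):
        from sklearn.linear_model import LogisticRegression

        X, y, _ = make_logistic_instance(seed, weighted=False)
        n = len(y)
        lam, alpha = 0.02, 0.4
        res = WeightedLogit(X, y, standardize=False).fit(lam, alpha, tol=1e-12)
        C = 1.0 / (n * lam * (2 - alpha))
        sk = LogisticRegression(
            penalty="elasticnet", solver="saga", C=C, l1_ratio=alpha / (2 - alpha),
            tol=1e-12, max_iter=1_000_000,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            sk.fit(X, y)
        np.testing.assert_allclose(res.coefficients, sk.coef_[0], atol=1e-8)
        assert res.intercept == pytest.approx(sk.intercept_[0], abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_scaling_reduction_identity(self, seed):
        """Rescaling columns by 1/w and fitting plain EN reproduces the
        weighted objective (both penalties act on w∘β)."""
        X, y, w = make_logistic_instance(seed)
        lam, alpha = 0.03, 0.6
        direct = WeightedLogit(X, y, penalty_weights=w, standardize=False).fit(
            lam, alpha, tol=1e-10
        )
        scaled = WeightedLogit(X / w, y, standardize=False).fit(lam, alpha, tol=1e-10)
        beta_back = scaled.coefficients / w
        obj_back = penalized_objective(
            X, y, beta_back, scaled.intercept, PenaltyConfig(lam, alpha, w)
        )
        assert obj_back == pytest.approx(direct.objective, abs=1e-6)

    def test_zero_weight_gene_is_never_dropped(self):
        rng = np.random.default_rng(7)
        n = 120
        x_signal = rng.standard_normal(n)
        from scipy.special import expit

        y = (rng.random(n) < expit(2.0 * x_signal)).astype(float)
        X = np.column_stack([x_signal, rng.standard_normal((n, 3))])
        w = np.array([0.0, 1.0, 1.0, 1.0])
        m = WeightedLogit(X, y, penalty_weights=w, standardize=False)
        for lam in [0.01, 0.1, 1.0, 100.0]:
            res = m.fit(lam, 0.5)
            assert res.coefficients[0] != 0.0

    def test_selection_monotone_along_lambda_path(self):
        X, y, _ = make_logistic_instance(4, n=80, p=15, weighted=False)
        m = WeightedLogit(X, y)
        fits = m.fit_path(0.5, n_lambda=30)
        counts = [f.n_selected for f in fits]
        # allow rare ±1 tolerance-induced violations
        violations = sum(1 for a, b in zip(counts, counts[1:]) if b < a - 1)
        assert violations == 0
        assert counts[0] == 0  # path starts at lambda_max

    def test_objective_decreases_with_lambda_relaxation(self):
        X, y, w = make_logistic_instance(5)
        m = WeightedLogit(X, y, penalty_weights=w, standardize=False)
        strong = m.fit(0.5, 0.5)
        weak = m.fit(0.005, 0.5)
        dev_strong = penalized_objective(X, y, strong.coefficients, strong.intercept,
                                         PenaltyConfig(1e-12, 0.5, w))
        dev_weak = penalized_objective(X, y, weak.coefficients, weak.intercept,
                                       PenaltyConfig(1e-12, 0.5, w))
        assert dev_weak <= dev_strong  # smaller penalty fits data at least as well

    def test_warm_start_agrees_with_cold_start(self):
        X, y, w = make_logistic_instance(6)
        m = WeightedLogit(X, y, penalty_weights=w)
        cold = m.fit(0.02, 0.5, tol=1e-9)
        warm = m.fit(0.02, 0.5, start=m.fit(0.1, 0.5), tol=1e-9)
        np.testing.assert_allclose(warm.coefficients, cold.coefficients, atol=1e-6)

    def test_standardized_and_raw_fits_agree_at_tiny_penalty(self):
        X, y, _ = make_logistic_instance(8, n=200, p=4, weighted=False)
        a = WeightedLogit(X, y, standardize=True).fit(1e-6, 0.5, tol=1e-10)
        b = WeightedLogit(X, y, standardize=False).fit(1e-6, 0.5, tol=1e-10)
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-3)


class TestCrossValidate:
    def test_singleton_grid_returns_that_configuration(self):
        X, y, _ = make_logistic_instance(0, weighted=False)
        m = WeightedLogit(X, y)
        cv = m.fit_cv(alpha_grid=[0.5], n_folds=3, n_lambda=1, seed=0)
        assert cv.config.alpha == 0.5
        assert cv.config.lam == pytest.approx(m.lambda_max(0.5))
        assert len(cv.cv_table) == 1

    def test_returned_config_attains_table_minimum(self):
        X, y, _ = make_logistic_instance(1, n=90, p=8, weighted=False)
        m = WeightedLogit(X, y)
        cv = m.fit_cv(alpha_grid=[0.3, 0.7], n_folds=4, n_lambda=8, seed=1)
        best_row = cv.cv_table.loc[
            (cv.cv_table.alpha == cv.config.alpha)
            & (cv.cv_table.lam == cv.config.lam)
        ]
        assert np.isclose(best_row.mse_mean.iloc[0], cv.cv_table.mse_mean.min())

    def test_class_too_small_for_folds_errors(self):
        X, y, _ = make_logistic_instance(2, n=20, p=4, weighted=False)
        y[:] = 0
        y[:3] = 1
        m = WeightedLogit(X, y)
        with pytest.raises(ValueError, match="stratified"):
            cross_validate(m, alpha_grid=[0.5], n_folds=10, n_lambda=2)

    def test_planted_signal_recovered_after_cv(self, medium_dataset):
        from sctwiner import make_labels, T_CORE, T_PERIPHERY, N_PERIPHERY
        from sctwiner.containers import align_expression

        (expr, ann, truth), design = medium_dataset
        labels, _ = make_labels(ann, [T_CORE, T_PERIPHERY], [N_PERIPHERY])
        em = align_expression(expr, labels)
        m = WeightedLogit(em.values, labels.values, gene_ids=list(em.gene_ids))
        cv = m.fit_cv(alpha_grid=[0.5], n_folds=5, n_lambda=20, seed=0)
        selected = set(cv.best_fit.selected_genes)
        planted = set(truth.discriminative_genes)
        assert len(selected & planted) >= 0.8 * len(planted)
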