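import numpy as np
import pytest

from connmvpa import (
    LabeledStudy,
    SvmConfig,
    generate_feature_dataset,
    loocv,
    rbf_kernel,
    sweep,
    train_svm,
)
from connmvpa.classify import _metrics, default_c_grid, default_k_grid

# analysis-scale penalty for unit-variance feature-level studies (see
# docs/methods.md: fixed by the hyperparameter-sweep procedure on pilots)
C_FEATURE = 0.755


class TestRbfKernel:
    def test_identical_vectors_give_one(self, rng):
        x = rng.standard_normal(6)
        assert rbf_kernel(x, x) == pytest.approx(1.0)

    def test_closed_form_value(self):
        # ||d||^2 = 8, sigma = 2 -> exp(-8/8) = e^-1
        x1 = np.zeros(2)
        x2 = np.array([2.0, 2.0])
        assert rbf_kernel(x1, x2, sigma=2.0) == pytest.approx(np.exp(-1), abs=1e-9)
        assert rbf_kernel(x1, x2, sigma=2.0) == pytest.approx(0.367879, abs=1e-6)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(10):
            a, b = rng.standard_normal((2, 5))
            k = rbf_kernel(a, b)
            assert k == pytest.approx(rbf_kernel(b, a))
            assert 0 < k <= 1

    def test_matches_sklearn_gamma_mapping(self, rng):
        from sklearn.metrics.pairwise import rbf_kernel as sk_rbf

        a, b = rng.standard_normal((2, 7))
        cfg = SvmConfig(sigma=2.0)
        assert rbf_kernel(a, b, 2.0) == pytest.approx(
            float(sk_rbf(a[None], b[None], gamma=cfg.gamma)[0, 0])
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(3), np.zeros(4))


class TestTrainSvm:
    def test_separable_classes_fit_perfectly(self):
        X = np.concatenate([np.full(10, -5.0), np.full(10, 5.0)])[:, None]
        X += np.linspace(-0.1, 0.1, 20)[:, None]
        y = np.repeat([-1, 1], 10)
        model = train_svm(X, y, SvmConfig(C=1.0))
        assert model.score(X, y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_svm(np.zeros((4, 2)), np.ones(4, dtype=int))

    def test_dual_coefficients_feasible(self, rng):
        """KKT dual feasibility: 0 <= alpha <= C and sum alpha_i y_i = 0."""
        X = rng.standard_normal((10, 3))
        y = np.repeat([1, -1], 5)
        C = 0.5
        model = train_svm(X, y, SvmConfig(C=C, sigma=2.0))
        signed_alpha = model.dual_coef_[0]  # alpha_i * y_i
        assert np.all(np.abs(signed_alpha) <= C + 1e-6)
        assert abs(signed_alpha.sum()) < 1e-6

    def test_margin_conditions_on_toy_problem(self, rng):
        """KKT: unbounded SVs sit on the margin |f| = 1 within tolerance."""
        X = np.concatenate([rng.normal(-2, 0.5, 5), rng.normal(2, 0.5, 5)])[:, None]
        y = np.repeat([-1, 1], 5)
        C = 10.0
        model = train_svm(X, y, SvmConfig(C=C, sigma=2.0))
        f = model.decision_function(X[model.support_])
        alpha = np.abs(model.dual_coef_[0])
        free = (alpha > 1e-8) & (alpha < C - 1e-8)
        assert free.any()
        assert np.allclose(np.abs(f[free]), 1.0, atol=1e-6)

    def test_duplicated_training_set_same_predictions(self, rng):
        X = rng.standard_normal((12, 4))
        y = np.resize([1, -1], 12)
        grid = rng.standard_normal((20, 4))
        cfg = SvmConfig(C=1.0)
        m1 = train_svm(X, y, cfg)
        m2 = train_svm(np.vstack([X, X]), np.concatenate([y, y]), cfg)
        assert np.array_equal(m1.predict(grid), m2.predict(grid))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SvmConfig(sigma=0)
        with pytest.raises(ValueError):
            SvmConfig(C=-1)
        with pytest.raises(ValueError):
            SvmConfig(k=0)


class TestMetrics:
    def test_printed_triple_arithmetic(self):
        """19/25 post and 17/25 pre correct -> GR 72%, sens 76%, spec 68%."""
        y_true = np.repeat([1, -1], 25)
        y_pred = y_true.copy()
        y_pred[:6] = -1  # 6 post misclassified -> 19 correct
        y_pred[25:33] = 1  # 8 pre misclassified -> 17 correct
        gr, sens, spec = _metrics(y_true, y_pred)
        assert (gr, sens, spec) == (0.72, 0.76, 0.68)

    def test_gr_decomposition(self, rng):
        y_true = rng.choice([1, -1], size=40)
        y_true[:2] = [1, -1]
        y_pred = rng.choice([1, -1], size=40)
        gr, sens, spec = _metrics(y_true, y_pred)
        n_post, n_pre = (y_true == 1).sum(), (y_true == -1).sum()
        assert gr == pytest.approx((sens * n_post + spec * n_pre) / 40)
        assert 0 <= gr <= 1 and 0 <= sens <= 1 and 0 <= spec <= 1


class TestLoocv:
    def test_fold_count_25_plus_25(self):
        study = generate_feature_dataset(n_per_class=25, n_features=30, seed=0)
        res = loocv(study, SvmConfig(k=10, C=C_FEATURE))
        assert res.n_folds == 50

    def test_strong_effect_classified(self, planted_feature_study):
        res = loocv(planted_feature_study, SvmConfig(k=10, C=C_FEATURE))
        assert res.gr >= 0.9

    def test_held_out_sample_cannot_leak_into_selection(self, planted_feature_study):
        cfg = SvmConfig(k=10, C=C_FEATURE)
        res = loocv(planted_feature_study, cfg)
        X2 = planted_feature_study.X.copy()
        X2[4] += 100.0  # corrupt one held-out sample
        study2 = LabeledStudy(
            X=X2, y=planted_feature_study.y,
            subject_ids=planted_feature_study.subject_ids,
        )
        res2 = loocv(study2, cfg)
        assert np.array_equal(res.folds[4].selected, res2.folds[4].selected)

    def test_fold_losing_a_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((5, 4))
        y = np.array([1, -1, -1, -1, -1])
        study = LabeledStudy(X=X, y=y, subject_ids=np.arange(5))
        with pytest.raises(ValueError, match="lose one class"):
            loocv(study, SvmConfig(k=2))

    def test_giant_sigma_degrades_gracefully(self, planted_feature_study):
        res = loocv(planted_feature_study, SvmConfig(k=10, C=1.0, sigma=1e6))
        assert 0.0 <= res.gr <= 1.0  # no crash; majority voting acceptable

    def test_decision_values_recorded_per_fold(self, planted_feature_study):
        res = loocv(planted_feature_study, SvmConfig(k=10, C=C_FEATURE))
        assert res.decision_values.shape == (50,)
        preds = np.where(res.decision_values > 0, 1, -1)
        assert np.array_equal(preds, [f.y_pred for f in res.folds])


class TestSweep:
    def test_grids_match_colon_notation(self):
        c = default_c_grid()
        assert c[0] == pytest.approx(0.005)
        assert c[1] - c[0] == pytest.approx(0.05)
        assert c[-1] <= 2.0 < c[-1] + 0.05
        k = default_k_grid()
        assert k[0] == 40 and k[-1] == 300

    def test_single_point_equals_loocv(self):
        study = generate_feature_dataset(
            n_per_class=8, n_features=20, informative_idx=(1, 2, 3),
            effect_size=2.0, seed=4,
        )
        cfg = SvmConfig(k=5, C=C_FEATURE)
        sw = sweep(study, k_grid=[5], c_grid=[C_FEATURE], config=cfg)
        res = loocv(study, cfg)
        assert sw.gr.shape == (1, 1)
        assert sw.best_gr == res.gr
        assert (sw.best_k, sw.best_c) == (5, C_FEATURE)

    def test_argmax_dominates_grid_and_is_deterministic(self):
        study = generate_feature_dataset(
            n_per_class=8, n_features=20, informative_idx=(1, 2, 3),
            effect_size=2.0, seed=4,
        )
        sw1 = sweep(study, k_grid=[3, 6], c_grid=[0.105, 0.755])
        sw2 = sweep(study, k_grid=[3, 6], c_grid=[0.105, 0.755])
        assert np.array_equal(sw1.gr, sw2.gr)
        assert sw1.best_gr == sw1.gr.max()
        # tie rule: argmax is the first (smallest-k, then smallest-C) maximum
        ia, ib = np.argwhere(sw1.gr == sw1.best_gr)[0]
        assert (sw1.best_k, sw1.best_c) == (sw1.k_grid[ia], sw1.c_grid[ib])

    def test_empty_grid_rejected(self, planted_feature_study):
        with pytest.raises(ValueError):
            sweep(planted_feature_study, k_grid=[], c_grid=[0.1])
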