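"""Ridge-logistic cost, solver, cross-validation, AUC and window sweep."""

import math

import numpy as np
import pytest

from taskdecomp import (
    ScenarioParams,
    auc,
    classify,
    cost,
    cross_validate,
    fit,
    frame_window_sweep,
    gen_gaussian,
    gen_motion_trials,
    predict_proba,
)
from taskdecomp.errors import DataError, ParameterError, StratificationError
from taskdecomp.logistic import default_lambda_grid, sigmoid


class TestCost:
    def test_null_model_on_balanced_labels_equals_log2(self):
        x = np.zeros((6, 3))
        d = np.array([0, 1, 0, 1, 0, 1])
        assert cost(0.0, np.zeros(3), x, d, 0.0) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_perfect_prediction_drives_cost_to_zero(self):
        x = np.array([[-1.0], [1.0]])
        d = np.array([0, 1])
        assert cost(0.0, np.array([400.0]), x, d, 0.0) < 1e-10

    def test_matches_hand_evaluated_formula(self):
        """Two trials, hand-set parameters, evaluated by explicit arithmetic."""
        x = np.array([[0.5, -1.0], [2.0, 0.25]])
        d = np.array([1, 0])
        w0, w, lam = 0.3, np.array([0.7, -0.2]), 0.11
        z = w0 + x @ w
        f = 1.0 / (1.0 + np.exp(-z))
        expected = -(math.log(f[0]) + math.log(1 - f[1])) / 2 + lam / 2 * (
            0.7**2 + 0.2**2
        )
        assert cost(w0, w, x, d, lam) == pytest.approx(expected, abs=1e-12)

    def test_stable_at_extreme_scores(self):
        x = np.array([[1.0], [-1.0]])
        d = np.array([1, 0])
        c = cost(0.0, np.array([500.0]), x, d, 0.0)
        assert np.isfinite(c) and c < 1e-12

    def test_negative_lambda_rejected(self):
        with pytest.raises(ParameterError):
            cost(0.0, np.zeros(1), np.zeros((2, 1)), np.array([0, 1]), -1.0)


def _finite_diff_grad(w0, w, x, d, lam, eps=1e-6):
    beta = np.concatenate([[w0], w])
    g = np.zeros_like(beta)
    for i in range(len(beta)):
        bp, bm = beta.copy(), beta.copy()
        bp[i] += eps
        bm[i] -= eps
        g[i] = (
            cost(bp[0], bp[1:], x, d, lam) - cost(bm[0], bm[1:], x, d, lam)
        ) / (2 * eps)
    return g


class TestFit:
    def test_gradient_matches_central_differences(self):
        """Analytic gradient agrees with finite differences to 1e-6 relative."""
        from taskdecomp.logistic import _grad

        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 4))
        d = rng.integers(0, 2, size=12)
        for _ in range(5):
            w0 = rng.normal()
            w = rng.normal(size=4)
            lam = rng.uniform(0.01, 1.0)
            analytic, _ = _grad(w0, w, x, d, lam)
            numeric = _finite_diff_grad(w0, w, x, d, lam)
            np.testing.assert_allclose(analytic, numeric, rtol=1e-6, atol=1e-9)

    def test_matches_grid_search_on_1d_problem(self):
        """Fitted (w0, w) matches a refined grid search of the cost surface."""
        x = np.array([[-1.0], [-1.0], [1.0], [1.0], [-1.0], [1.0]])
        d = ((x[:, 0] + 1) / 2).astype(int)
        lam = 1.0
        m = fit(x, d, lam=lam)

        # independent oracle: iterative grid refinement over (w0, w)
        lo = np.array([-3.0, -3.0])
        hi = np.array([3.0, 3.0])
        best = None
        for _ in range(8):
            g0 = np.linspace(lo[0], hi[0], 31)
            g1 = np.linspace(lo[1], hi[1], 31)
            vals = np.array(
                [[cost(a, np.array([b]), x, d, lam) for b in g1] for a in g0]
            )
            i, j = np.unravel_index(np.argmin(vals), vals.shape)
            best = (g0[i], g1[j])
            span0 = (hi[0] - lo[0]) / 10
            span1 = (hi[1] - lo[1]) / 10
            lo = np.array([best[0] - span0, best[1] - span1])
            hi = np.array([best[0] + span0, best[1] + span1])
        assert m.w0 == pytest.approx(best[0], abs=1e-4)
        assert m.w[0] == pytest.approx(best[1], abs=1e-4)

    def test_solution_beats_random_parameters(self):
        """Convexity: the solver's cost is below 100 random (w0, w) draws."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 3))
        d = rng.integers(0, 2, size=30)
        lam = 0.1
        m = fit(x, d, lam=lam)
        for _ in range(100):
            w0 = rng.normal(scale=2)
            w = rng.normal(scale=2, size=3)
            assert m.final_cost <= cost(w0, w, x, d, lam) + 1e-12

    def test_ridge_shrinkage_monotone_in_lambda(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(200, 3))
        d = rng.permutation(np.repeat([0, 1], 100))
        norms = [
            np.linalg.norm(fit(x, d, lam=lam).w) for lam in (0.01, 0.1, 1.0, 10.0)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_row_duplication_leaves_fit_unchanged(self):
        """The cost is a per-trial mean, so duplicating all rows is a no-op."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 2))
        d = rng.integers(0, 2, size=20)
        m1 = fit(x, d, lam=0.5)
        m2 = fit(np.vstack([x, x]), np.concatenate([d, d]), lam=0.5)
        assert m1.w0 == pytest.approx(m2.w0, abs=1e-6)
        np.testing.assert_allclose(m1.w, m2.w, atol=1e-6)

    def test_separable_data_without_penalty_flags_nonconvergence(self):
        x = np.array([[-1.0], [-2.0], [1.0], [2.0]])
        d = np.array([0, 0, 1, 1])
        with pytest.warns(RuntimeWarning, match="separable"):
            m = fit(x, d, lam=0.0, max_iter=50)
        assert not m.converged

    def test_single_class_rejected(self):
        with pytest.raises(DataError, match="both classes"):
            fit(np.zeros((4, 1)), np.zeros(4, dtype=int), lam=0.1)

    def test_agrees_with_sklearn_at_matched_penalty(self):
        """Independent cross-check: sklearn minimizes sum-CE + w'w/(2C); with
        C = 1/(T*lambda) both objectives coincide."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(4)
        x = rng.normal(size=(80, 3))
        z = 0.5 + x @ np.array([1.0, -2.0, 0.5])
        d = (rng.random(80) < sigmoid(z)).astype(int)
        lam = 0.05
        ours = fit(x, d, lam=lam)
        ref = LogisticRegression(
            C=1.0 / (80 * lam), tol=1e-10, max_iter=5000
        ).fit(x, d)
        np.testing.assert_allclose(ours.w, ref.coef_[0], atol=1e-5)
        assert ours.w0 == pytest.approx(ref.intercept_[0], abs=1e-5)


class TestPredictClassify:
    def test_null_model_predicts_half(self):
        from taskdecomp import LogisticModel

        m = LogisticModel(w0=0.0, w=np.zeros(2), lam=0.0)
        np.testing.assert_array_equal(
            predict_proba(m, np.ones((3, 2))), np.full(3, 0.5)
        )

    def test_extreme_scores_do_not_overflow(self):
        from taskdecomp import LogisticModel

        m = LogisticModel(w0=0.0, w=np.array([500.0]), lam=0.0)
        p = predict_proba(m, np.array([[1.0], [-1.0]]))
        assert p[0] == pytest.approx(1.0) and p[1] == pytest.approx(0.0)
        assert np.all(np.isfinite(p))

    def test_bias_cancels_score(self):
        from taskdecomp import LogisticModel

        m = LogisticModel(w0=1.0, w=np.array([1.0]), lam=0.0)
        assert predict_proba(m, np.array([[-1.0]]))[0] == pytest.approx(0.5)

    def test_threshold_and_tie_rule(self):
        from taskdecomp import LogisticModel

        m = LogisticModel(w0=0.0, w=np.array([1.0]), lam=0.0)
        x = np.array([[-0.04], [0.04], [0.0]])  # p ~ 0.49, 0.51, exactly 0.5
        labels = classify(m, x)
        np.testing.assert_array_equal(labels, [0, 1, 0])

    def test_recovers_planted_labels_on_separated_data(self):
        fm, d, _ = gen_gaussian(
            ScenarioParams(n_per_class=50, n_features=2, delta=8, seed=5)
        )
        m = fit(fm, d, lam=1e-3)
        np.testing.assert_array_equal(classify(m, fm), np.asarray(d))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=30)
        s[::3] = np.round(s[::3], 1)  # force some ties
        d = rng.integers(0, 2, size=30)
        if d.sum() in (0, 30):
            d[0] = 1 - d[0]
        total = 0.0
        pairs = 0
        for i in np.flatnonzero(d == 1):
            for j in np.flatnonzero(d == 0):
                total += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
                pairs += 1
        assert auc(s, d) == pytest.approx(total / pairs, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            auc([0.1, 0.2], [1, 1])


class TestCrossValidate:
    GRID = np.logspace(-4, 0, 8)

    def test_same_seed_bitwise_reproducible(self):
        fm, d, _ = gen_gaussian(
            ScenarioParams(n_per_class=25, n_features=3, delta=2, seed=7)
        )
        a = cross_validate(fm, d, lambda_grid=self.GRID, k=5, repeats=2, seed=42)
        b = cross_validate(fm, d, lambda_grid=self.GRID, k=5, repeats=2, seed=42)
        assert a.chosen_lambda == b.chosen_lambda
        np.testing.assert_array_equal(a.mean_cv_cost, b.mean_cv_cost)
        assert a.accuracy_mean == b.accuracy_mean
        for fa, fb in zip(a.fold_assignments, b.fold_assignments):
            np.testing.assert_array_equal(fa, fb)

    def test_well_separated_data_classified_above_95_percent(self):
        """Planted separation of 6 sd (Bayes accuracy ~0.999), T=100."""
        fm, d, _ = gen_gaussian(
            ScenarioParams(n_per_class=50, n_features=2, delta=6, seed=8)
        )
        cv = cross_validate(fm, d, lambda_grid=self.GRID, k=10, repeats=2, seed=0)
        assert cv.accuracy_mean > 0.95
        assert 0.95 < cv.auc_mean <= 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(9)
        fm, d, _ = gen_gaussian(
            ScenarioParams(n_per_class=60, n_features=2, delta=4, seed=9)
        )
        perm = rng.permutation(np.asarray(d))
        cv = cross_validate(fm.X, perm, lambda_grid=self.GRID, k=10, repeats=2, seed=1)
        assert abs(cv.accuracy_mean - 0.5) < 0.15

    def test_chosen_lambda_in_grid(self):
        fm, d, _ = gen_gaussian(
            ScenarioParams(n_per_class=20, n_features=2, delta=2, seed=10)
        )
        cv = cross_validate(fm, d, lambda_grid=self.GRID, k=5, repeats=1, seed=2)
        assert cv.chosen_lambda in self.GRID
        assert 0.0 <= cv.accuracy_mean <= 1.0

    def test_too_few_trials_per_class_raises_stratification_error(self):
        x = np.random.default_rng(0).normal(size=(6, 2))
        d = np.array([0, 0, 0, 0, 0, 1])
        with pytest.raises(StratificationError):
            cross_validate(x, d, lambda_grid=self.GRID, k=5, repeats=1, seed=0)

    def test_default_grid_spans_four_decades(self):
        fm, d, _ = gen_gaussian(
            ScenarioParams(n_per_class=20, n_features=2, delta=2, seed=11)
        )
        grid = default_lambda_grid(fm, d)
        assert len(grid) == 50
        assert np.log10(grid.max() / grid.min()) == pytest.approx(4.0)


@pytest.fixture(scope="module")
def planted_window_trials():
    """Class signal confined to the last 4 frames of a 2-joint series."""
    j, f_signal = 2, 4
    d_feat = j * f_signal
    w = np.ones(d_feat)  # joint-major: signal in every frame of the window
    w /= np.linalg.norm(w)
    params = ScenarioParams(
        n_per_class=30,
        n_features=d_feat,
        delta=5.0,
        sigma_irr=0.5,
        w_true=w,
        seed=12,
    )
    return gen_motion_trials(
        params, n_joints=j, window_frames=f_signal, n_frames=20,
        baseline_noise_sd=0.5,
    )


class TestFrameWindowSweep:
    def test_accuracy_plateaus_at_planted_support(self, planted_window_trials):
        ts, truth = planted_window_trials
        res = frame_window_sweep(
            ts, max_frames=6, lambda_grid=np.logspace(-3, 0, 4), k=5,
            repeats=1, seed=3,
        )
        acc = res.table.set_index("window_frames")["accuracy_mean"]
        assert acc.loc[4:].min() > 0.9  # plateau at/after the planted width
        assert acc.loc[1] < acc.loc[4:].max() + 1e-9
        assert 1 <= res.best_window <= 6

    def test_pure_noise_stays_at_chance(self):
        params = ScenarioParams(
            n_per_class=25, n_features=2 * 3, delta=0.0, seed=13
        )
        ts, _ = gen_motion_trials(
            params, n_joints=2, window_frames=3, n_frames=12
        )
        res = frame_window_sweep(
            ts, max_frames=3, lambda_grid=np.logspace(-2, 0, 3), k=5,
            repeats=1, seed=4,
        )
        assert (res.table["accuracy_mean"] - 0.5).abs().max() < 0.2

    def test_rows_equal_per_window_cross_validate_calls(self, tiny_sweep=None):
        from taskdecomp import build_feature_matrix

        params = ScenarioParams(n_per_class=15, n_features=2 * 3, delta=3, seed=14)
        ts, _ = gen_motion_trials(params, n_joints=2, window_frames=3, n_frames=10)
        grid = np.logspace(-2, 0, 3)
        res = frame_window_sweep(ts, max_frames=3, lambda_grid=grid, k=5,
                                 repeats=1, seed=5)
        for f in (1, 2, 3):
            fm, d = build_feature_matrix(ts, f)
            cv = cross_validate(fm, d, lambda_grid=grid, k=5, repeats=1, seed=5)
            row = res.table[res.table["window_frames"] == f].iloc[0]
            assert row["accuracy_mean"] == cv.accuracy_mean
            assert row["chosen_lambda"] == cv.chosen_lambda
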