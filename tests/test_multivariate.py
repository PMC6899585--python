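import numpy as np
import pytest

from cadtrace.multivariate import (MultivariateError, ScaledData, SelectionParams,
                                   SPlotPoint, fit_oplsda, fit_oplsda_auto,
                                   fit_pca, q2_cross_validation, scale_matrix,
                                   select_differential, splot)


def nipals_pls1(X, y, tol=1e-12, max_iter=500):
    """Independent NIPALS PLS1 oracle: first component of centered-y PLS."""
    yc = y - y.mean()
    u = yc.copy()
    w_old = None
    for _ in range(max_iter):
        w = X.T @ u / (u @ u)
        w = w / np.linalg.norm(w)
        t = X @ w
        q = yc @ t / (t @ t)
        u = yc * q
        if w_old is not None and np.linalg.norm(w - w_old) < tol:
            break
        w_old = w
    return w, X @ w


def _random_scaled(rng, n=10, k=6):
    X = rng.normal(size=(n, k))
    return scale_matrix(X, "center")


class TestScaling:
    def test_centering_zeroes_column_means(self, rng):
        data = scale_matrix(rng.normal(2.0, 1.0, (8, 5)), "center")
        assert np.allclose(data.X.mean(axis=0), 0, atol=1e-12)

    def test_unit_variance_gives_unit_sd(self, rng):
        data = scale_matrix(rng.normal(0, 3.0, (8, 5)), "unit_variance")
        assert np.allclose(data.X.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_constant_columns_dropped_with_warning(self, rng):
        X = rng.normal(size=(6, 4))
        X[:, 2] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            data = scale_matrix(X, "unit_variance")
        assert data.X.shape[1] == 3

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(MultivariateError):
            scale_matrix(rng.normal(size=(4, 3)), "autoscale")


class TestPca:
    def test_rank_one_matrix_pc1_explains_everything(self):
        X = np.outer(np.arange(1.0, 7.0), np.array([1.0, 2.0, -1.0]))
        data = scale_matrix(X, "center")
        res = fit_pca(data, 1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_reconstruction_matches_input(self, rng):
        data = scale_matrix(rng.normal(size=(8, 20)), "center")
        rank = min(data.X.shape)
        res = fit_pca(data, rank)
        assert np.allclose(res.scores @ res.loadings.T, data.X, atol=1e-8)

    def test_duplicated_samples_get_identical_scores(self, rng):
        X = rng.normal(size=(4, 6))
        X = np.vstack([X, X[0]])
        res = fit_pca(scale_matrix(X, "center"), 2)
        assert np.allclose(res.scores[0], res.scores[-1], atol=1e-10)

    def test_explained_variance_non_increasing(self, rng):
        res = fit_pca(_random_scaled(rng, 9, 7), 5)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
        assert res.explained_variance_ratio.sum() <= 1 + 1e-12


def _classed_data(rng, n_per=5, k=12, effect=2.0):
    y = np.array([1.0] * n_per + [-1.0] * n_per)
    X = rng.normal(size=(2 * n_per, k))
    X[:, :3] += effect * y[:, None]
    return scale_matrix(X, "unit_variance"), y


class TestOplsda:
    def test_zero_orthogonal_equals_nipals_pls1(self, rng):
        X = rng.normal(size=(10, 6))
        y = np.array([1.0] * 5 + [-1.0] * 5)
        data = scale_matrix(X, "center")
        model = fit_oplsda(data, y, 0)
        w_ref, t_ref = nipals_pls1(data.X, y)
        if t_ref[y > 0].mean() < 0:
            w_ref, t_ref = -w_ref, -t_ref
        assert np.allclose(model.w, w_ref, atol=1e-10)
        assert np.allclose(model.t, t_ref, atol=1e-10)

    def test_predictive_scores_orthogonal_to_orthogonal_scores(self, rng):
        data, y = _classed_data(rng, n_per=6, k=15)
        model = fit_oplsda(data, y, 3)
        for j in range(model.n_orthogonal):
            t_o = model.t_orth[:, j]
            assert abs(model.t @ t_o) < 1e-8 * np.linalg.norm(model.t) * np.linalg.norm(t_o)

    def test_variance_bookkeeping_sums_to_one(self, rng):
        data, y = _classed_data(rng, n_per=6, k=15)
        model = fit_oplsda(data, y, 2)
        X = data.X.copy()
        for j in range(model.n_orthogonal):
            X = X - np.outer(model.t_orth[:, j], model.p_orth[:, j])
        X = X - np.outer(model.t, model.p)
        residual = np.sum(X ** 2) / np.sum(data.X ** 2)
        assert model.r2x_predictive + model.r2x_orthogonal + residual == \
            pytest.approx(1.0, abs=1e-8)
        assert model.r2x_predictive + model.r2x_orthogonal <= 1 + 1e-8

    def test_sample_permutation_permutes_scores_only(self, rng):
        data, y = _classed_data(rng)
        model = fit_oplsda(data, y, 1)
        perm = rng.permutation(len(y))
        data_p = ScaledData(data.X[perm], data.scaling, data.means, data.scales)
        model_p = fit_oplsda(data_p, y[perm], 1)
        assert np.allclose(model_p.t, model.t[perm], atol=1e-10)
        assert np.allclose(model_p.p, model.p, atol=1e-10)

    def test_single_class_rejected(self, rng):
        data = _random_scaled(rng)
        with pytest.raises(MultivariateError):
            fit_oplsda(data, np.ones(data.X.shape[0]), 0)

    def test_too_many_orthogonal_components_rejected(self, rng):
        data, y = _classed_data(rng, n_per=3, k=4)
        with pytest.raises(MultivariateError):
            fit_oplsda(data, y, 12)


class TestQ2:
    def test_separable_data_has_high_q2(self, rng):
        # large effect, low noise: half the features carry the class signal
        data, y = _classed_data(rng, n_per=6, k=12, effect=3.0)
        X = data.X.copy()
        X[:, :6] = 0.2 * X[:, :6] + 3.0 * y[:, None]
        data = scale_matrix(X, "unit_variance")
        assert q2_cross_validation(data, y, folds=6, seed=0) > 0.5

    def test_shuffled_labels_average_q2_nonpositive(self, rng):
        data, y = _classed_data(rng, n_per=6, k=40, effect=3.0)
        q2s = []
        for _ in range(20):
            y_perm = rng.permutation(y)
            if len(np.unique(y_perm)) < 2:
                continue
            q2s.append(q2_cross_validation(data, y_perm, folds=4, seed=1))
        assert np.mean(q2s) < 0.1

    def test_smallest_valid_case_returns_finite_value(self, rng):
        X = rng.normal(size=(4, 5))
        y = np.array([1.0, 1.0, -1.0, -1.0])
        q2 = q2_cross_validation(scale_matrix(X, "center"), y, folds=2, seed=0)
        assert np.isfinite(q2)

    def test_auto_fit_reports_q2_and_caps_components(self, rng):
        data, y = _classed_data(rng, n_per=6, k=30)
        model = fit_oplsda_auto(data, y, folds=4, seed=0, max_orthogonal=2)
        assert model.q2_cumulative is not None
        assert model.n_orthogonal <= 2


class TestSplot:
    def test_matches_direct_covariance_and_correlation(self, rng):
        data, y = _classed_data(rng, n_per=6, k=9)
        model = fit_oplsda(data, y, 1)
        points = splot(model, data)
        for j, pt in enumerate(points):
            cov = np.cov(model.t, data.X[:, j], ddof=1)[0, 1]
            corr = np.corrcoef(model.t, data.X[:, j])[0, 1]
            assert pt.p1 == pytest.approx(cov, abs=1e-10)
            assert pt.pcorr == pytest.approx(corr, abs=1e-10)

    def test_perfect_correlate_column_has_unit_pcorr(self, rng):
        # noise columns orthogonal to y, so t is exactly proportional to y
        y = np.array([1.0] * 5 + [-1.0] * 5)
        noise = rng.normal(size=(10, 4))
        noise -= np.outer(y, y @ noise) / (y @ y)
        X = np.column_stack([y, noise])
        data = scale_matrix(X, "center")
        model = fit_oplsda(data, y, 0)
        points = splot(model, data)
        assert abs(points[0].pcorr) == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_feature_has_near_zero_p1(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.column_stack([y, np.array([1.0, -1.0, 1.0, -1.0])])
        data = scale_matrix(X, "center")
        model = fit_oplsda(data, y, 0)
        points = splot(model, data)
        assert abs(points[1].p1) < 1e-10

    def test_p1_is_bilinear_pcorr_scale_free(self, rng):
        data, y = _classed_data(rng)
        model = fit_oplsda(data, y, 0)
        pt = splot(model, data)[0]
        data2 = ScaledData(data.X * 2, data.scaling, data.means, data.scales)
        model2 = fit_oplsda(data2, y, 0)
        assert np.allclose(model2.t, 2 * model.t)  # t = Xw scales with X
        pt2 = splot(model2, data2)[0]
        assert pt2.p1 == pytest.approx(4 * pt.p1, rel=1e-10)
        assert pt2.pcorr == pytest.approx(pt.pcorr, rel=1e-10)

    def test_zero_variance_feature_flagged(self, rng):
        y = np.array([1.0] * 3 + [-1.0] * 3)
        X = rng.normal(size=(6, 3))
        X[:, 2] = 7.0
        data = scale_matrix(X, "center")
        model = fit_oplsda(data, y, 0)
        points = splot(model, data)
        assert points[2].zero_variance and points[2].pcorr == 0.0


class TestSelection:
    def test_empty_points_give_empty_sets(self):
        case, control = select_differential([], SelectionParams())
        assert case == [] and control == []

    def test_positive_point_assigned_to_case(self):
        pt = SPlotPoint(0, 0.03, 0.5)
        case, control = select_differential([pt], SelectionParams())
        assert case == [pt] and control == []

    def test_both_cutoffs_required(self):
        params = SelectionParams()
        assert select_differential([SPlotPoint(0, 0.03, 0.01)], params) == ([], [])
        assert select_differential([SPlotPoint(0, 0.01, 0.5)], params) == ([], [])

    def test_monotone_in_cutoffs(self, rng):
        points = [SPlotPoint(j, rng.normal(), float(np.clip(rng.normal(), -1, 1)))
                  for j in range(200)]
        prev = None
        for cut in (0.01, 0.05, 0.2, 0.5):
            case, control = select_differential(points, SelectionParams(cut, cut))
            size = len(case) + len(control)
            if prev is not None:
                assert size <= prev
            prev = size

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(MultivariateError):
            SelectionParams(0.0, 0.02)
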