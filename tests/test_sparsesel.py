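"""Group-lasso solver correctness: KKT certificates, closed forms, and
agreement with an independent proximal-gradient oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from utfbssp import (
    GroupedFeatureMatrix,
    fit_group_lasso,
    group_coefficient_distribution,
    lambda_max,
    regularization_path,
    select_features,
)
from utfbssp.sparsesel import path_summary_to_csv


# --- independent oracle: FISTA (accelerated proximal gradient) -------------

def fista_group_lasso(U, y, groups, lam, n_iter=30_000):
    """Proximal-gradient minimizer of ||y - U a||^2 + lam sum_g ||a_g||.

    A different algorithm from the block-coordinate solver under test:
    full-gradient steps with the group soft-threshold proximal operator and
    Nesterov acceleration.
    """
    L = 2.0 * np.linalg.norm(U, ord=2) ** 2  # Lipschitz constant of the gradient
    step = 1.0 / L
    a = np.zeros(U.shape[1])
    z = a.copy()
    t = 1.0
    for _ in range(n_iter):
        grad = 2.0 * U.T @ (U @ z - y)
        v = z - step * grad
        new = np.zeros_like(v)
        for g in groups:
            ng = np.linalg.norm(v[g])
            if ng > step * lam:
                new[g] = v[g] * (1.0 - step * lam / ng)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = new + ((t - 1.0) / t_new) * (new - a)
        a, t = new, t_new
    return a


def objective(U, y, groups, lam, a):
    r = y - U @ a
    return float(r @ r + lam * sum(np.linalg.norm(a[g]) for g in groups))


def random_instance(rng, m=None, p=None, k=None):
    m = m or int(rng.integers(10, 41))
    k = k or int(rng.integers(2, 7))
    sizes = rng.integers(1, 5, size=k)
    p = int(sizes.sum())
    U = rng.standard_normal((m, p))
    y = rng.standard_normal(m)
    groups, start = [], 0
    for s in sizes:
        groups.append(np.arange(start, start + s))
        start += s
    return GroupedFeatureMatrix(U, groups, y)


class TestLambdaMax:
    def test_zero_response_gives_zero(self, rng):
        feat = GroupedFeatureMatrix(rng.standard_normal((5, 4)),
                                    [np.arange(2), np.arange(2, 4)], np.zeros(5))
        assert lambda_max(feat, center=False, standardize=False) == 0.0

    def test_identity_design_single_group(self, rng):
        y = rng.standard_normal(6)
        feat = GroupedFeatureMatrix(np.eye(6), [np.arange(6)], y)
        lmax = lambda_max(feat, center=False, standardize=False)
        assert lmax == pytest.approx(2.0 * np.linalg.norm(y))
        at = fit_group_lasso(feat, 1.001 * lmax, center=False, standardize=False)
        assert np.all(at.a == 0.0)
        below = fit_group_lasso(feat, 0.99 * lmax, center=False, standardize=False)
        assert np.linalg.norm(below.a) > 0

    def test_fit_above_lambda_max_is_exactly_zero(self, rng):
        for _ in range(5):
            feat = random_instance(rng)
            lmax = lambda_max(feat, center=False, standardize=False)
            m = fit_group_lasso(feat, 1.001 * lmax, center=False, standardize=False)
            assert np.all(m.a == 0.0)
            assert m.selected.size == 0


class TestSolver:
    def test_unpenalized_fit_equals_least_squares(self, rng):
        U = rng.standard_normal((30, 8))
        y = rng.standard_normal(30)
        feat = GroupedFeatureMatrix(U, [np.arange(4), np.arange(4, 8)], y)
        m = fit_group_lasso(feat, 0.0, center=False, standardize=False)
        ols, *_ = np.linalg.lstsq(U, y, rcond=None)
        np.testing.assert_allclose(m.a, ols, atol=1e-7)

    def test_orthonormal_design_closed_form(self, rng):
        # with U'U = I the block solution is group soft-thresholding of U'y
        q, _ = np.linalg.qr(rng.standard_normal((20, 8)))
        U = q[:, :8]
        y = rng.standard_normal(20)
        groups = [np.arange(0, 3), np.arange(3, 5), np.arange(5, 8)]
        feat = GroupedFeatureMatrix(U, groups, y)
        lam = 1.5
        m = fit_group_lasso(feat, lam, center=False, standardize=False)
        b = U.T @ y
        for g in groups:
            nb = np.linalg.norm(b[g])
            expected = b[g] * max(0.0, 1.0 - lam / (2.0 * nb))
            np.testing.assert_allclose(m.a[g], expected, atol=1e-8)

    def test_objective_matches_fista_oracle(self, rng):
        for _ in range(20):
            feat = random_instance(rng)
            lmax = lambda_max(feat, center=False, standardize=False)
            lam = float(rng.uniform(0.05, 0.8)) * lmax
            m = fit_group_lasso(feat, lam, center=False, standardize=False)
            a_oracle = fista_group_lasso(feat.U, feat.y, feat.groups, lam)
            obj_oracle = objective(feat.U, feat.y, feat.groups, lam, a_oracle)
            assert m.objective <= obj_oracle + 1e-5
            assert abs(m.objective - obj_oracle) < 1e-5

    def test_kkt_certificate_at_convergence(self, rng):
        for _ in range(10):
            feat = random_instance(rng)
            lmax = lambda_max(feat, center=False, standardize=False)
            lam = 0.3 * lmax
            m = fit_group_lasso(feat, lam, tol=1e-8, center=False, standardize=False)
            assert m.converged
            r = feat.y - feat.U @ m.a
            for g in feat.groups:
                grad = 2.0 * feat.U[:, g].T @ r
                ng = np.linalg.norm(m.a[g])
                if ng > 1e-10:
                    np.testing.assert_allclose(grad, lam * m.a[g] / ng, atol=1e-7)
                else:
                    assert np.linalg.norm(grad) <= lam + 1e-7

    def test_objective_non_increasing_in_sweep_count(self, rng):
        feat = random_instance(rng, m=30)
        lam = 0.2 * lambda_max(feat, center=False, standardize=False)
        objs = []
        import warnings
        for it in range(1, 8):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fit_group_lasso(feat, lam, tol=1e-14, max_iter=it,
                                    center=False, standardize=False)
            objs.append(m.objective)
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_nan_inputs_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            GroupedFeatureMatrix(np.array([[np.nan, 1.0]]), [np.arange(2)],
                                 np.array([1.0]))

    def test_negative_penalty_rejected(self, rng):
        feat = random_instance(rng)
        with pytest.raises(ValueError):
            fit_group_lasso(feat, -1.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_solution_satisfies_kkt_for_arbitrary_instances(self, seed):
        rng = np.random.default_rng(seed)
        feat = random_instance(rng)
        lam = float(rng.uniform(0.0, 1.2)) * max(
            lambda_max(feat, center=False, standardize=False), 1e-6
        )
        m = fit_group_lasso(feat, lam, tol=1e-9, center=False, standardize=False)
        assert m.converged
        assert m.kkt_residual <= 1e-9 * 1.01 + 1e-12


class TestPath:
    def test_grid_above_lambda_max_gives_single_zero_model(self, rng):
        feat = random_instance(rng)
        lmax = lambda_max(feat, center=False, standardize=False)
        models = regularization_path(feat, np.array([1.1 * lmax]),
                                     center=False, standardize=False)
        assert len(models) == 1 and np.all(models[0].a == 0.0)

    def test_grid_reaching_zero_recovers_least_squares(self, rng):
        U = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        feat = GroupedFeatureMatrix(U, [np.arange(3), np.arange(3, 6)], y)
        lmax = lambda_max(feat, center=False, standardize=False)
        models = regularization_path(feat, np.array([lmax, 0.1 * lmax, 0.0]),
                                     center=False, standardize=False)
        ols, *_ = np.linalg.lstsq(U, y, rcond=None)
        np.testing.assert_allclose(models[-1].a, ols, atol=1e-7)

    def test_planted_group_enters_the_path_first(self, rng):
        # orthogonal groups, one carrying all the signal: its screening
        # correlation 2||U_g'y|| is largest, so it must activate first
        q, _ = np.linalg.qr(rng.standard_normal((40, 12)))
        U = q[:, :12]
        groups = [np.arange(i * 3, (i + 1) * 3) for i in range(4)]
        a_true = np.zeros(12)
        a_true[groups[2]] = [2.0, -1.5, 1.0]
        y = U @ a_true + 0.05 * rng.standard_normal(40)
        feat = GroupedFeatureMatrix(U, groups, y)
        scores = [2 * np.linalg.norm(U[:, g].T @ y) for g in groups]
        assert np.argmax(scores) == 2  # oracle confirms the plant dominates
        lmax = lambda_max(feat, center=False, standardize=False)
        models = regularization_path(
            feat, lmax * np.array([0.99, 0.9, 0.7, 0.5]),
            center=False, standardize=False,
        )
        first_nonempty = next(m for m in models if m.selected.size)
        assert first_nonempty.selected.tolist() == [2]

    def test_descending_grid_enforced(self, rng):
        feat = random_instance(rng)
        with pytest.raises(ValueError, match="descending"):
            regularization_path(feat, np.array([0.1, 1.0]))


class TestSelection:
    def test_all_groups_selected_returns_identical_design(self, rng):
        feat = random_instance(rng)
        m = fit_group_lasso(feat, 0.0, center=False, standardize=False)
        reduced = select_features(m, feat)
        np.testing.assert_array_equal(reduced.U, feat.U)
        assert len(reduced.groups) == len(feat.groups)

    def test_bookkeeping_keeps_band_indices_of_selected_groups(self, rng):
        U = rng.standard_normal((20, 8))
        groups = [np.arange(0, 2), np.arange(2, 4), np.arange(4, 6), np.arange(6, 8)]
        feat = GroupedFeatureMatrix(U, groups, rng.standard_normal(20),
                                    band_indices=np.array([10, 20, 30, 40]))
        m = fit_group_lasso(feat, 0.0, center=False, standardize=False)
        m.selected = np.array([1, 3])
        reduced = select_features(m, feat)
        assert reduced.U.shape[1] == 4
        np.testing.assert_array_equal(reduced.band_indices, [20, 40])
        np.testing.assert_array_equal(reduced.U, U[:, [2, 3, 6, 7]])

    def test_empty_selection_falls_back_to_best_screening_group(self, rng):
        feat = random_instance(rng)
        lmax = lambda_max(feat, center=False, standardize=False)
        m = fit_group_lasso(feat, 2.0 * lmax, center=False, standardize=False)
        assert m.selected.size == 0
        with pytest.warns(UserWarning, match="screening"):
            reduced = select_features(m, feat)
        assert len(reduced.groups) == 1

    def test_group_coefficient_distribution_matches_direct_norms(self, rng):
        feat = random_instance(rng)
        lam = 0.3 * lambda_max(feat, center=False, standardize=False)
        m = fit_group_lasso(feat, lam, center=False, standardize=False)
        dist = group_coefficient_distribution(m)
        expected = [np.linalg.norm(m.a[g]) for g in feat.groups]
        np.testing.assert_allclose(dist, expected, atol=1e-12)
        assert np.all(dist >= 0)
        assert np.all(dist[np.setdiff1d(np.arange(feat.n_groups), m.selected)] == 0)

    def test_hand_built_norm(self):
        feat = GroupedFeatureMatrix(np.eye(4), [np.arange(2), np.arange(2, 4)],
                                    np.zeros(4))
        m = fit_group_lasso(feat, 0.0, center=False, standardize=False)
        m.coef_std = None
        m.a = np.array([0.0, 0.0, 3.0, 4.0])
        np.testing.assert_allclose(group_coefficient_distribution(m), [0.0, 5.0])


class TestStandardizedMode:
    def test_predictions_invariant_to_column_scaling_at_lam_zero(self, rng):
        U = rng.standard_normal((30, 6)) * np.array([1.0, 10.0, 0.1, 5.0, 1.0, 2.0])
        y = rng.standard_normal(30)
        feat = GroupedFeatureMatrix(U, [np.arange(3), np.arange(3, 6)], y)
        m = fit_group_lasso(feat, 0.0, center=True, standardize=True)
        ols, *_ = np.linalg.lstsq(np.column_stack([U, np.ones(30)]), y, rcond=None)
        np.testing.assert_allclose(m.predict(U), U @ ols[:6] + ols[6], atol=1e-6)

    def test_standardized_selection_ignores_raw_column_scale(self, rng):
        feat = random_instance(rng, m=30)
        lam = 0.3 * lambda_max(feat, center=True, standardize=True)
        m1 = fit_group_lasso(feat, lam, center=True, standardize=True)
        scaled = GroupedFeatureMatrix(feat.U * 100.0, feat.groups, feat.y)
        m2 = fit_group_lasso(scaled, lam, center=True, standardize=True)
        np.testing.assert_array_equal(m1.selected, m2.selected)
        np.testing.assert_allclose(m1.coef_std, m2.coef_std, atol=1e-6)


def test_path_summary_csv(tmp_path, rng):
    feat = random_instance(rng)
    lmax = lambda_max(feat, center=False, standardize=False)
    models = regularization_path(feat, lmax * np.array([1.1, 0.3, 0.1]),
                                 center=False, standardize=False)
    path = tmp_path / "path.csv"
    path_summary_to_csv(models, path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["lambda", "n_selected", "objective",
                                "selected_band_indices"]
    assert df.loc[0, "n_selected"] == 0
    assert (df["n_selected"].to_numpy() == [m.selected.size for m in models]).all()
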