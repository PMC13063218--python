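"""Maximum-likelihood PCA: reductions, self-consistency, and projections."""

import numpy as np
import pytest

from mlpcalr import ErrorCovariance, fit_mlpca, fit_rank_grid, ml_project, objective_s2
from mlpcalr.mlpca import reconstruct


def random_pd(rng, m, floor=0.1):
    a = rng.normal(size=(m, m))
    return a @ a.T + floor * np.eye(m)


def classical_pca_reconstruction(x, p):
    mu = x.mean(axis=0)
    u, s, vt = np.linalg.svd(x - mu, full_matrices=False)
    return u[:, :p] * s[:p] @ vt[:p] + mu


class TestCaseReductions:
    def test_case_a_equals_classical_pca(self, rng):
        for _ in range(10):
            x = rng.normal(size=(10, 6))
            model = fit_mlpca(x, None, p=3, case_id="A")
            np.testing.assert_allclose(
                reconstruct(model, model.scores),
                classical_pca_reconstruction(x, 3),
                atol=1e-10,
            )

    def test_scaled_identity_ecm_equals_pca(self, rng):
        """Any sigma^2 I error structure reduces case D to classical PCA."""
        x = rng.normal(size=(9, 5))
        ecm = ErrorCovariance(3.7 * np.eye(5))
        model = fit_mlpca(x, ecm, p=2, case_id="D", ridge=0.0)
        np.testing.assert_allclose(
            reconstruct(model, model.scores),
            classical_pca_reconstruction(x, 2),
            atol=1e-9,
        )

    def test_case_b_equals_case_d_for_diagonal_ecm(self, rng):
        x = rng.normal(size=(8, 5))
        ecm = ErrorCovariance(np.diag(rng.uniform(0.5, 2.0, 5)))
        mb = fit_mlpca(x, ecm, p=2, case_id="B", ridge=0.0)
        md = fit_mlpca(x, ecm, p=2, case_id="D", ridge=0.0)
        np.testing.assert_allclose(
            reconstruct(mb, mb.scores), reconstruct(md, md.scores), atol=1e-9
        )

    def test_iterative_cases_rejected(self, rng):
        with pytest.raises(NotImplementedError, match="iterative"):
            fit_mlpca(rng.normal(size=(5, 4)), ErrorCovariance(np.eye(4)), 1, case_id="C")


class TestObjective:
    def test_full_rank_residual_is_zero(self, rng):
        x = rng.normal(size=(8, 5))
        ecm = ErrorCovariance(random_pd(rng, 5))
        model = fit_mlpca(x, ecm, p=5, case_id="D", ridge=0.0)
        assert model.s2 == pytest.approx(0.0, abs=1e-16)

    def test_identity_ecm_reduces_to_ssr(self, rng):
        x = rng.normal(size=(7, 4))
        ecm = ErrorCovariance(np.eye(4))
        model = fit_mlpca(x, ecm, p=2, case_id="D", ridge=0.0)
        t = ml_project(model, x)
        ssr = np.sum((x - reconstruct(model, t)) ** 2)
        assert objective_s2(model, x, ecm) == pytest.approx(ssr, rel=1e-10)

    def test_fit_s2_equals_direct_evaluation(self, rng):
        x = rng.normal(size=(9, 6))
        ecm = ErrorCovariance(random_pd(rng, 6))
        model = fit_mlpca(x, ecm, p=2, case_id="D", ridge=0.0)
        assert model.s2 == pytest.approx(objective_s2(model, x, ecm), rel=1e-6)

    def test_diagonal_ecm_matches_per_sample_loop(self, rng):
        x = rng.normal(size=(3, 4))
        d = rng.uniform(0.5, 2.0, 4)
        ecm = ErrorCovariance(np.diag(d))
        model = fit_mlpca(x, ecm, p=1, case_id="D", ridge=0.0)
        t = ml_project(model, x)
        resid = x - reconstruct(model, t)
        by_hand = sum(float(r @ np.diag(1 / d) @ r) for r in resid)
        assert objective_s2(model, x, ecm) == pytest.approx(by_hand, rel=1e-10)


class TestProjection:
    def test_subspace_point_is_fixed(self, rng):
        x = rng.normal(size=(8, 5))
        ecm = ErrorCovariance(random_pd(rng, 5))
        model = fit_mlpca(x, ecm, p=2, case_id="D", ridge=0.0)
        point = reconstruct(model, np.array([1.3, -0.7]))
        t = ml_project(model, point)
        np.testing.assert_allclose(reconstruct(model, t), point, atol=1e-8)

    def test_matches_generalized_least_squares_formula(self, rng):
        x = rng.normal(size=(8, 5))
        sigma = random_pd(rng, 5)
        model = fit_mlpca(x, ErrorCovariance(sigma), p=2, case_id="D", ridge=0.0)
        v = rng.normal(size=5)
        p_mat = model.loadings
        sinv = np.linalg.inv(sigma + model.ridge * np.eye(5))
        expected = np.linalg.solve(
            p_mat.T @ sinv @ p_mat, p_mat.T @ sinv @ (v - model.center)
        )
        np.testing.assert_allclose(ml_project(model, v), expected, atol=1e-8)

    def test_training_scores_reproduced(self, rng):
        x = rng.normal(size=(10, 6))
        model = fit_mlpca(x, ErrorCovariance(random_pd(rng, 6)), p=3, case_id="D", ridge=0.0)
        np.testing.assert_allclose(ml_project(model, x), model.scores, atol=1e-8)

    def test_identity_sigma_is_ols_projection(self, rng):
        x = rng.normal(size=(8, 5))
        model = fit_mlpca(x, None, p=2, case_id="A")
        v = rng.normal(size=5)
        ols = np.linalg.lstsq(model.loadings, v - model.center, rcond=None)[0]
        np.testing.assert_allclose(ml_project(model, v), ols, atol=1e-9)


class TestRankGrid:
    def test_case_a_grid_is_nested(self, rng):
        x = rng.normal(size=(10, 6))
        grid = fit_rank_grid(x, None, p_max=4, case_id="A")
        full = grid[-1]
        for model in grid:
            np.testing.assert_allclose(
                np.abs(model.loadings), np.abs(full.loadings[:, : model.p]), atol=1e-9
            )

    def test_s2_non_increasing_and_refit_consistent(self, rng):
        x = rng.normal(size=(10, 6))
        ecm = ErrorCovariance(random_pd(rng, 6))
        grid = fit_rank_grid(x, ecm, p_max=5, case_id="D", ridge=0.0)
        s2 = [m.s2 for m in grid]
        assert all(s2[i + 1] <= s2[i] + 1e-12 for i in range(4))
        for p, model in enumerate(grid, start=1):
            scratch = fit_mlpca(x, ecm, p, case_id="D", ridge=0.0)
            assert model.s2 == pytest.approx(scratch.s2, rel=1e-10)

    def test_p_out_of_range(self, rng):
        x = rng.normal(size=(5, 4))
        with pytest.raises(ValueError):
            fit_mlpca(x, None, p=5, case_id="A")  # p > n-1 with centering
        with pytest.raises(ValueError):
            fit_rank_grid(x, None, p_max=5, case_id="A")


class TestSubspaceProperties:
    def test_reconstruction_invariant_to_basis_rotation(self, rng):
        x = rng.normal(size=(9, 5))
        ecm = ErrorCovariance(random_pd(rng, 5))
        model = fit_mlpca(x, ecm, p=2, case_id="D", ridge=0.0)
        rec = reconstruct(model, ml_project(model, x))
        rot = np.linalg.qr(rng.normal(size=(2, 2)))[0]
        rotated = fit_mlpca(x, ecm, p=2, case_id="D", ridge=0.0)
        rotated.loadings = rotated.loadings @ rot
        rotated.whitened_loadings = rotated.whitened_loadings @ rot
        rec2 = reconstruct(rotated, ml_project(rotated, x))
        np.testing.assert_allclose(rec2, rec, atol=1e-8)

    def test_whitened_loadings_orthonormal(self, rng):
        x = rng.normal(size=(9, 5))
        model = fit_mlpca(x, ErrorCovariance(random_pd(rng, 5)), p=3, case_id="D", ridge=0.0)
        np.testing.assert_allclose(
            model.whitened_loadings.T @ model.whitened_loadings, np.eye(3), atol=1e-10
        )

    def test_case_d_beats_case_a_under_correlated_noise(self):
        """Averaged subspace recovery: the weighted fit is at least as good."""
        from scipy.linalg import subspace_angles

        m, n = 20, 100
        base = np.random.default_rng(0)
        a = base.normal(size=(m, m))
        sigma = a @ a.T / m + 0.05 * np.eye(m)
        chol = np.linalg.cholesky(sigma)
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            v = np.linalg.qr(rng.normal(size=(m, 2)))[0]
            t = rng.normal(scale=[3.0, 1.5], size=(n, 2))
            x = t @ v.T + rng.normal(size=(n, m)) @ chol.T
            ecm = ErrorCovariance(sigma)
            ang_d = np.degrees(subspace_angles(fit_mlpca(x, ecm, 2, "D").loadings, v)).max()
            ang_a = np.degrees(subspace_angles(fit_mlpca(x, None, 2, "A").loadings, v)).max()
            diffs.append(ang_a - ang_d)
        assert np.mean(diffs) > 0
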