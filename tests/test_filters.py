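"""Filter recursions: factorization, equivalences, stability, divergence."""

import numpy as np
import pytest

from countssm.filters import (
    FilterConfig,
    FilterStatus,
    NotPositiveSemidefiniteError,
    iekf_filter,
    linear_kalman_filter,
    svd_factorize,
    svd_iekf_filter,
)
from countssm.model import (
    ArmaComponent,
    DrugComponent,
    ModelMatrices,
    ObservationFunction,
    StateSpaceModel,
)


def scalar_matrices(a=1.0, q=1.0, r=1.0):
    return ModelMatrices(
        A=np.array([[a]]),
        Q=np.array([[q]]),
        R=np.array([[r]]),
        C=np.array([[1.0]]),
        Bu=np.zeros((1, 1)),
        block_index=[],
    )


class TestSvdFactorize:
    def test_identity(self):
        f = svd_factorize(np.eye(3))
        np.testing.assert_allclose(f.sigma, [1, 1, 1])

    def test_diagonal(self):
        f = svd_factorize(np.diag([4.0, 1.0]))
        np.testing.assert_allclose(f.sigma, [2.0, 1.0])

    def test_random_reconstruction(self, rng):
        for _ in range(100):
            A = rng.standard_normal((4, 4))
            M = A.T @ A
            f = svd_factorize(M)
            err = np.linalg.norm(f.reconstruct() - M) / np.linalg.norm(M)
            assert err < 1e-10
            # factor invariants
            assert np.max(np.abs(f.W.T @ f.W - np.eye(4))) < 1e-10
            assert np.all(f.sigma >= 0)
            assert np.all(np.diff(f.sigma) <= 1e-12)

    def test_not_psd_raises(self):
        with pytest.raises(NotPositiveSemidefiniteError):
            svd_factorize(np.diag([1.0, -0.5]))

    def test_rank_deficient_ok(self):
        M = np.outer([1.0, 2.0], [1.0, 2.0])
        f = svd_factorize(M)
        np.testing.assert_allclose(f.reconstruct(), M, atol=1e-12)


class TestLinearKalman:
    def test_riccati_steady_state(self):
        """a=q=c=r=1: predicted variance converges to the golden ratio."""
        mat = scalar_matrices()
        T = 200
        out = linear_kalman_filter(mat, np.zeros(T), np.zeros((T, 1)))
        assert out.P_pred[-1, 0, 0] == pytest.approx((1 + np.sqrt(5)) / 2, abs=1e-8)

    def test_noise_free_identity_tracks_data(self):
        """Constant-state model observed without noise: the filtered state
        locks onto the data immediately."""
        mat = scalar_matrices(a=1.0, q=0.0, r=1e-14)
        y = np.full(30, 2.5)
        out = linear_kalman_filter(mat, y, np.zeros((30, 1)))
        np.testing.assert_allclose(out.x_filt[:, 0], y, atol=1e-5)

    def test_loglik_matches_reference_recursion(self, rng):
        """Hand-rolled dense KF + Gaussian logpdf terms as the oracle."""
        from scipy.stats import norm

        a, q, r = 0.8, 0.5, 0.3
        mat = scalar_matrices(a, q, r)
        T = 50
        y = rng.standard_normal(T)
        out = linear_kalman_filter(mat, y, np.zeros((T, 1)))

        x, P, ll = 0.0, 1.0, 0.0
        for t in range(T):
            xp = a * x
            Pp = a * P * a + q
            v = Pp + r
            nu = y[t] - xp
            ll += norm.logpdf(nu, scale=np.sqrt(v))
            K = Pp / v
            x = xp + K * nu
            P = (1 - K) * Pp
        assert out.loglik == pytest.approx(ll, abs=1e-10)


class TestIekfEquivalences:
    def test_identity_observation_matches_linear_kf(self, default_sim, default_model):
        model = default_model.with_updates(obs_kind="identity")
        mat = model.matrices()
        f = model.observation()
        y, u = default_sim.counts.astype(float), default_sim.dosages
        lk = linear_kalman_filter(mat, y, u)
        ik = iekf_filter(mat, f, y, u)
        sk = svd_iekf_filter(mat, f, y, u)
        assert ik.loglik == pytest.approx(lk.loglik, abs=1e-6)
        assert sk.loglik == pytest.approx(lk.loglik, abs=1e-6)
        np.testing.assert_allclose(ik.x_filt, lk.x_filt, atol=1e-8)
        np.testing.assert_allclose(sk.x_filt, lk.x_filt, atol=1e-7)

    def test_svd_matches_dense_iekf_on_adh(self, default_sim, default_model):
        mat = default_model.matrices()
        f = default_model.observation()
        y, u = default_sim.counts.astype(float), default_sim.dosages
        dense = iekf_filter(mat, f, y, u)
        sqrt_ = svd_iekf_filter(mat, f, y, u)
        assert dense.ok and sqrt_.ok
        assert np.max(np.abs(dense.x_filt - sqrt_.x_filt)) < 1e-6
        assert sqrt_.loglik == pytest.approx(dense.loglik, abs=1e-6)

    def test_svd_innovation_variance_matches_dense(self, default_sim, default_model):
        mat = default_model.matrices()
        f = default_model.observation()
        y, u = default_sim.counts.astype(float), default_sim.dosages
        dense = iekf_filter(mat, f, y, u)
        sqrt_ = svd_iekf_filter(mat, f, y, u)
        np.testing.assert_allclose(
            sqrt_.innovation_var, dense.innovation_var, rtol=1e-8
        )


class TestSvdPreArrays:
    def test_scalar_time_update(self):
        """a=1, P0=1, q=1: pre-array [1;1] has singular value sqrt(2),
        so the predicted variance is 2 = a P a + q."""
        mat = scalar_matrices(a=1.0, q=1.0, r=1.0)
        f = ObservationFunction("identity", c_row=[1.0])
        out = svd_iekf_filter(mat, f, np.array([0.0]), np.zeros((1, 1)))
        assert out.P_pred[0, 0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_zero_q_identity_a_preserves_prior(self):
        mat = scalar_matrices(a=1.0, q=0.0, r=1.0)
        f = ObservationFunction("identity", c_row=[1.0])
        out = svd_iekf_filter(mat, f, np.array([0.0]), np.zeros((1, 1)))
        assert out.P_pred[0, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_all_covariances_psd(self, default_sim, default_model):
        mat = default_model.matrices()
        f = default_model.observation()
        out = svd_iekf_filter(
            mat, f, default_sim.counts.astype(float), default_sim.dosages
        )
        for P in (out.P_pred, out.P_filt):
            mins = np.array([np.linalg.eigvalsh(Pt).min() for Pt in P])
            assert mins.min() >= -1e-10


class TestIterationBehavior:
    def test_inner_iteration_converges_on_default_scenario(
        self, default_sim, default_model
    ):
        cfg = FilterConfig()
        out = svd_iekf_filter(
            default_model.matrices(),
            default_model.observation(),
            default_sim.counts.astype(float),
            default_sim.dosages,
            cfg,
        )
        assert out.ok
        assert np.all(out.iter_counts < cfg.iter_max)
        # every recorded trace ends below the stopping tolerance
        for trace in out.iter_traces:
            assert trace[-1] < cfg.iter_tol

    def test_iter_counts_bounded_by_iter_max(self, default_sim, default_model):
        cfg = FilterConfig(iter_max=3)
        out = svd_iekf_filter(
            default_model.matrices(),
            default_model.observation(),
            default_sim.counts.astype(float),
            default_sim.dosages,
            cfg,
        )
        assert np.all(out.iter_counts <= 3)

    def test_exponential_blowup_sets_diverged_status(self, default_sim):
        comps = [
            DrugComponent(0.989, 8.0, 0),
            DrugComponent(0.9, 5.0, 1),
            DrugComponent(0.9, 5.0, 2),
            ArmaComponent(1.2, -0.35, 0.2, 0.08),
        ]
        model = StateSpaceModel(
            components=comps, obs_noise_var=0.04, obs_kind="exponential",
            control_dim=3,
        )
        y, u = default_sim.counts.astype(float), default_sim.dosages
        for fn in (iekf_filter, svd_iekf_filter):
            out = fn(model.matrices(), model.observation(), y, u)
            assert out.status is FilterStatus.DIVERGED
            assert out.failure_time is not None
            assert np.isneginf(out.loglik)


class TestValidation:
    def test_filter_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(iter_tol=0.0)
        with pytest.raises(ValueError):
            FilterConfig(iter_max=0)

    def test_length_mismatch_rejected(self):
        mat = scalar_matrices()
        with pytest.raises(ValueError):
            linear_kalman_filter(mat, np.zeros(5), np.zeros((4, 1)))

    def test_control_dim_mismatch_rejected(self):
        mat = scalar_matrices()
        with pytest.raises(ValueError):
            linear_kalman_filter(mat, np.zeros(5), np.zeros((5, 2)))
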