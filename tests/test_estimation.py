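"""Likelihood, AICc, parameter transforms, fitting, ensembles, error bars."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from countssm.estimation import (
    ParameterTransform,
    aicc,
    errors_from_hessian,
    fit_ensemble,
    fit_model,
    hessian_std_errors,
    innovation_loglik,
    numerical_hessian,
)
from countssm.filters import FilterOutput, FilterStatus
from countssm.model import ArmaComponent, DrugComponent, StateSpaceModel

LOG2PI = np.log(2 * np.pi)


def _fo(nu, V):
    nu = np.asarray(nu, dtype=float)
    V = np.asarray(V, dtype=float)
    T = len(nu)
    return FilterOutput(
        x_pred=np.zeros((T, 1)),
        P_pred=np.zeros((T, 1, 1)),
        x_filt=np.zeros((T, 1)),
        P_filt=np.zeros((T, 1, 1)),
        innovations=nu,
        innovation_var=V,
        loglik_terms=-0.5 * (np.log(V) + nu**2 / V + LOG2PI),
        iter_counts=np.ones(T, dtype=np.int64),
        iter_traces=[np.empty(0)] * T,
    )


class TestInnovationLoglik:
    def test_zero_innovations_unit_variance(self):
        assert innovation_loglik(_fo(np.zeros(10), np.ones(10))) == pytest.approx(
            -5 * LOG2PI, abs=1e-12
        )

    def test_single_term(self):
        assert innovation_loglik(_fo([0.0], [1.0])) == pytest.approx(
            -0.5 * LOG2PI, abs=1e-12
        )

    def test_matches_gaussian_logpdf_sum(self, rng):
        from scipy.stats import norm

        nu = rng.standard_normal(40)
        V = rng.uniform(0.2, 3.0, 40)
        expected = norm.logpdf(nu, scale=np.sqrt(V)).sum()
        assert innovation_loglik(_fo(nu, V)) == pytest.approx(expected, abs=1e-10)

    def test_failed_filter_rejected(self):
        fo = _fo([0.0], [1.0])
        fo.status = FilterStatus.DIVERGED
        with pytest.raises(ValueError):
            innovation_loglik(fo)


class TestAicc:
    def test_reference_value(self):
        assert aicc(-100.0, 5, 100) == pytest.approx(210.63830, abs=1e-5)

    def test_zero_parameters(self):
        assert aicc(-42.0, 0, 50) == 84.0

    def test_strictly_increasing_in_npar(self):
        vals = [aicc(-100.0, p, 100) for p in range(0, 50)]
        assert np.all(np.diff(vals) > 0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            aicc(-1.0, 10, 11)


class TestParameterTransform:
    @given(
        ar=st.floats(0.001, 0.98),
        gain=st.floats(-3, 3),
        a2=st.floats(-0.9, 0.9),
        frac=st.floats(-0.95, 0.95),
        b1=st.floats(-2, 2),
        sigma=st.floats(1e-3, 5),
        r_excess=st.floats(1e-3, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_pack_unpack_round_trip(self, ar, gain, a2, frac, b1, sigma, r_excess):
        model = StateSpaceModel(
            components=[
                DrugComponent(0.5, 0.0, 0),
                ArmaComponent(0.5, 0.1, 0.0, 1.0),
            ],
            obs_noise_var=1.0,
        )
        tr = ParameterTransform(model)
        a1 = frac * (1 - a2)  # anywhere inside the stationarity triangle
        theta = np.array(
            [ar, gain, a1, a2, b1, sigma, tr.obs_noise_floor + r_excess]
        )
        np.testing.assert_allclose(tr.unpack(tr.pack(theta)), theta, atol=1e-12)

    def test_npar_counts_free_parameters(self, default_model):
        tr = ParameterTransform(default_model)
        # 3 drugs x (ar, gain) + ARMA (a1, a2, b1, sigma) + r
        assert tr.npar == 11
        assert len(tr.names) == 11

    def test_unpacked_parameters_always_valid(self, rng):
        model = StateSpaceModel(
            components=[DrugComponent(0.5, 0.0), ArmaComponent(0.5, 0.1, 0.0, 1.0)],
            obs_noise_var=1.0,
        )
        tr = ParameterTransform(model)
        for _ in range(100):
            phi = rng.uniform(-10, 10, tr.npar)
            tr.model_from_natural(tr.unpack(phi)).matrices()  # must not raise


def _simulate_linear(model, u, rng):
    """Simulate data directly from a model with identity observation."""
    mat = model.matrices()
    arma = [c for c in model.components if isinstance(c, ArmaComponent)]
    x = np.zeros(mat.m)
    y = np.empty(len(u))
    for t in range(len(u)):
        x = mat.A @ x + mat.Bu @ u[t]
        if arma:
            g = np.array([1.0, arma[0].ma_coeff])
            x[-2:] += arma[0].noise_sd * g * rng.standard_normal()
        y[t] = mat.C[0] @ x + np.sqrt(model.obs_noise_var) * rng.standard_normal()
    return y


class TestFitModel:
    def test_recovers_noise_scales_from_own_data(self):
        """Median over seeds of the ML estimates of sigma and r lands within
        20% of the generating values for a linear-Gaussian model."""
        truth = StateSpaceModel(
            components=[ArmaComponent(0.8, -0.2, 0.3, 1.0)],
            obs_noise_var=0.5,
            obs_kind="identity",
            control_dim=1,
        )
        u = np.zeros((500, 1))
        sigmas, rs = [], []
        for seed in range(10):
            y = _simulate_linear(truth, u, np.random.default_rng(seed))
            res = fit_model(truth, y, u, filter_kind="kf")
            sigmas.append(res.params["arma_sigma"])
            rs.append(res.params["r"])
        assert np.median(sigmas) == pytest.approx(1.0, rel=0.2)
        assert np.median(rs) == pytest.approx(0.5, rel=0.2)

    def test_negative_gain_sign_recovered(self):
        """A seizure-reducing drug (gain -0.4) with little noise keeps its
        sign in at least 9 of 10 random-restart fits."""
        truth = StateSpaceModel(
            components=[DrugComponent(0.5, -0.4, 0)],
            obs_noise_var=0.01,
            obs_kind="identity",
            control_dim=1,
        )
        T = 200
        u = np.zeros((T, 1))
        u[T // 4 :, 0] = 2.0
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = _simulate_linear(truth, u, rng)
            tr = ParameterTransform(truth, obs_noise_floor=1e-6)
            init = tr.random_natural(rng)
            res = fit_model(
                truth, y, u, init=init, filter_kind="kf", obs_noise_floor=1e-6
            )
            hits += res.params["drug1_gain"] < 0
        assert hits >= 9

    def test_series_shorter_than_parameters_rejected(self, small_model):
        with pytest.raises(ValueError):
            fit_model(small_model, np.ones(5), np.zeros((5, 1)))


class TestEnsemble:
    def test_singleton_ensemble_equals_single_fit(self, small_model):
        rng = np.random.default_rng(3)
        y = rng.poisson(1.5, 120).astype(float)
        u = np.zeros((120, 1))
        u[40:, 0] = 1.0
        ens = fit_ensemble(small_model, y, u, size=1, seed=3)
        tr = ParameterTransform(small_model)
        init = tr.random_natural(np.random.default_rng(3))
        single = fit_model(small_model, y, u, init=init)
        assert ens.members[0].params == single.params
        assert ens.best.loglik == single.loglik

    def test_seed_determinism(self, small_model):
        rng = np.random.default_rng(4)
        y = rng.poisson(1.5, 100).astype(float)
        u = np.linspace(0, 2, 100)[:, None]
        a = fit_ensemble(small_model, y, u, size=2, seed=9)
        b = fit_ensemble(small_model, y, u, size=2, seed=9)
        for ma, mb in zip(a.members, b.members):
            assert ma.params == mb.params
            assert ma.loglik == mb.loglik

    def test_best_member_has_min_aicc_and_consistency(self, small_model):
        rng = np.random.default_rng(5)
        y = rng.poisson(1.5, 100).astype(float)
        u = np.linspace(0, 2, 100)[:, None]
        ens = fit_ensemble(small_model, y, u, size=3, seed=1)
        ok_aiccs = [m.aicc for m in ens.members if m.converged]
        assert ens.best.aicc == min(ok_aiccs)
        # equal-npar members: lower AICc iff higher loglik
        for m in ens.members:
            if m.converged:
                assert m.aicc == pytest.approx(
                    aicc(m.loglik, m.npar, len(y)), abs=1e-9
                )
        table = ens.gain_vs_aicc()
        assert set(table.columns) == {"member", "drug", "gain", "aicc", "status"}
        assert len(table) == 3  # one drug per member

    def test_invalid_size_rejected(self, small_model):
        with pytest.raises(ValueError):
            fit_ensemble(small_model, np.ones(50), np.zeros((50, 1)), size=0, seed=0)


class TestHessianErrors:
    def test_quadratic_curvature(self):
        lam = 4.0
        H = numerical_hessian(lambda t: 0.5 * lam * t[0] ** 2, np.array([0.3]))
        err, flag = errors_from_hessian(H)
        assert flag == "ok"
        assert err[0] == pytest.approx(1 / np.sqrt(lam), rel=1e-6)

    def test_variance_mle_asymptotics(self, rng):
        """Curvature-based error of a Gaussian variance MLE approximates
        the asymptotic sd sqrt(2 sigma^4 / T)."""
        T, s2 = 1000, 1.3
        x = rng.standard_normal(T) * np.sqrt(s2)

        def negll(theta):
            v = theta[0]
            return 0.5 * (T * np.log(v) + np.sum(x**2) / v + T * LOG2PI)

        v_hat = np.mean(x**2)
        H = numerical_hessian(negll, np.array([v_hat]))
        err, flag = errors_from_hessian(H)
        assert flag == "ok"
        assert err[0] == pytest.approx(np.sqrt(2 * v_hat**2 / T), rel=0.3)

    def test_flat_direction_flagged(self):
        H = numerical_hessian(
            lambda t: (t[0] - t[1]) ** 2, np.array([0.0, 0.0])
        )
        err, flag = errors_from_hessian(H)
        assert flag == "singular"
        assert np.all(np.isnan(err))

    def test_attaches_errors_to_fit_result(self, small_model):
        rng = np.random.default_rng(6)
        y = rng.poisson(1.5, 100).astype(float)
        u = np.linspace(0, 2, 100)[:, None]
        res = fit_model(small_model, y, u)
        hessian_std_errors(res)
        assert res.std_errors is not None
        assert set(res.std_errors) == set(res.params)
        assert res.std_errors_flag in ("ok", "not_positive_definite", "singular")
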