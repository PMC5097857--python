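"""Solver contracts: block updates, convergence, and the contraction fixture."""

import math

import numpy as np
import pytest

from halfgraph.admm import (
    ADMMConfig,
    ADMMState,
    GAMMA_CONTRACTION,
    admm_step,
    contraction_matrix,
    fit_lvggm,
    x_update,
)
from halfgraph.objective import PenaltyConfig, SampleCovariance, objective
from halfgraph.simulate import sample_gaussian

from reference_convex import solve_convex_lvggm


class TestXUpdate:
    def test_identity_fixed_point(self):
        p = 4
        out = x_update(np.eye(p), np.eye(p), np.zeros((p, p)), np.zeros((p, p)), 1.0)
        np.testing.assert_allclose(out, np.eye(p), atol=1e-12)

    def test_scalar_closed_form(self):
        # B = 3, rho = 1: x = (3 + sqrt(13)) / 2, satisfying x - 1/x = 3
        Om = np.array([[4.0, 0.0], [0.0, 4.0]])
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = x_update(S, Om, np.zeros((2, 2)), np.zeros((2, 2)), 1.0)
        expected = (3.0 + math.sqrt(13.0)) / 2.0
        np.testing.assert_allclose(np.diag(out), expected)

    def test_stationarity_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            p = 6
            A = rng.normal(size=(p, p))
            S = A @ A.T / p + np.eye(p)
            Om = rng.normal(size=(p, p))
            Om = Om + Om.T
            L = np.zeros((p, p))
            Y = rng.normal(size=(p, p))
            Y = Y + Y.T
            rho = rng.uniform(0.5, 2.0)
            X = x_update(S, Om, L, Y, rho)
            B = rho * (Om - L) - Y - S
            np.testing.assert_allclose(rho * X - np.linalg.inv(X), B, atol=1e-10)
            assert np.linalg.eigvalsh(X)[0] > 0

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            x_update(np.eye(2), np.eye(2), np.zeros((2, 2)), np.zeros((2, 2)), 0.0)


class TestAdmmStep:
    def test_first_accelerated_step_is_plain(self):
        # alpha_1 = 1 gives gamma = 0: the step returns the hatted iterate
        S = np.eye(3)
        state = ADMMState.initial(3)
        cfg = PenaltyConfig(family="half", lam1=0.1, lam2=0.1)
        out_acc = admm_step(state, S, cfg, ADMMConfig(momentum="accelerated"))
        out_off = admm_step(state, S, cfg, ADMMConfig(momentum="off"))
        assert out_acc.gamma == 0.0
        np.testing.assert_allclose(out_acc.X, out_off.X)
        np.testing.assert_allclose(out_acc.Omega, out_off.Omega)

    def test_literal_mode_freezes_at_first_step(self):
        S = np.eye(3)
        state = ADMMState.initial(3)
        cfg = PenaltyConfig(family="half", lam1=0.1, lam2=0.1)
        out = admm_step(state, S, cfg, ADMMConfig(momentum="literal"))
        np.testing.assert_allclose(out.X, state.X)
        np.testing.assert_allclose(out.Omega, state.Omega)

    def test_huge_lam2_kills_lowrank(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(5, 5))
        S = A @ A.T / 5 + np.eye(5)
        state = ADMMState.initial(5)
        cfg = PenaltyConfig(family="half", lam1=0.0, lam2=1e3)
        out = admm_step(state, S, cfg, ADMMConfig())
        np.testing.assert_allclose(out.L, 0.0, atol=1e-12)

    def test_momentum_sequence(self):
        # alpha: 1 -> 1.618 -> 2.194; gamma_2 = 0.618/2.194 > 2 - sqrt(3)
        S = np.eye(3)
        cfg = PenaltyConfig(family="half", lam1=0.1, lam2=0.1)
        st = ADMMState.initial(3)
        st = admm_step(st, S, cfg, ADMMConfig())
        assert st.alpha == pytest.approx((1 + math.sqrt(5)) / 2)
        st = admm_step(st, S, cfg, ADMMConfig())
        assert st.gamma == pytest.approx(
            ((1 + math.sqrt(5)) / 2 - 1) / (0.5 * (1 + math.sqrt(1 + (1 + math.sqrt(5)) ** 2)))
        )
        assert st.gamma > GAMMA_CONTRACTION


class TestFitLVGGM:
    def test_unpenalized_limit_recovers_inverse(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            A = rng.normal(size=(10, 10))
            S = A @ A.T / 10 + np.eye(10)
            cfg = PenaltyConfig(family="half", lam1=0.0, lam2=0.0)
            est = fit_lvggm(S, cfg, ADMMConfig(max_iter=2000, tol_primal=1e-8, tol_change=1e-9))
            np.testing.assert_allclose(est.precision, np.linalg.inv(S), atol=1e-5)

    def test_independent_variables_give_empty_support(self):
        est = fit_lvggm(
            np.eye(12), PenaltyConfig(family="half", lam1=0.2, lam2=1.0), ADMMConfig()
        )
        assert est.support == set()
        np.testing.assert_allclose(est.L, 0.0, atol=1e-10)
        assert np.allclose(est.Omega, np.diag(np.diag(est.Omega)))

    def test_p2_unpenalized(self):
        Omega_true = np.array([[2.0, 0.8], [0.8, 1.5]])
        S = np.linalg.inv(Omega_true)
        cfg = PenaltyConfig(family="half", lam1=0.0, lam2=0.0)
        est = fit_lvggm(S, cfg, ADMMConfig(max_iter=2000, tol_primal=1e-8, tol_change=1e-9))
        np.testing.assert_allclose(est.precision, Omega_true, atol=1e-5)

    def test_nonconvergence_reports_not_raises(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(8, 8))
        S = A @ A.T / 8 + np.eye(8)
        est = fit_lvggm(S, PenaltyConfig(lam1=0.01, lam2=0.05), ADMMConfig(max_iter=3))
        assert not est.converged
        assert len(est.diagnostics["residuals"]) == 3

    def test_deterministic(self, bench_cov):
        cfg = PenaltyConfig(family="half", lam1=0.05, lam2=0.5)
        e1 = fit_lvggm(bench_cov, cfg, ADMMConfig(max_iter=50))
        e2 = fit_lvggm(bench_cov, cfg, ADMMConfig(max_iter=50))
        np.testing.assert_array_equal(e1.Omega, e2.Omega)

    def test_benchmark_fixture_contracts(self, bench_cov):
        """Residual, PD/PSD invariants and post-hoc contraction on the benchmark fit."""
        cfg = PenaltyConfig(family="half", lam1=0.08, lam2=0.5)
        acfg = ADMMConfig(rho=1.0, max_iter=500, keep_history=True, check_pd=True)
        est = fit_lvggm(bench_cov, cfg, acfg)
        res = est.diagnostics["residuals"]
        assert np.min(res) < 1e-5 and est.n_iter <= 500
        # PD/PSD at every recorded iterate
        for snap in est.diagnostics["history"]:
            X, _, L, _ = snap
            assert np.linalg.eigvalsh(X)[0] > 0
            assert np.linalg.eigvalsh(0.5 * (L + L.T))[0] > -1e-10
        # distance to the final iterate is nonincreasing once gamma exceeds
        # 2 - sqrt(3) (the positivity condition of the contraction coefficient)
        hist = est.diagnostics["history"]
        gammas = est.diagnostics["gammas"]
        final = hist[-1]
        dists = [np.linalg.norm(h - final) for h in hist]
        start = next(i for i, g in enumerate(gammas) if g > GAMMA_CONTRACTION)
        for a, b in zip(dists[start:-1], dists[start + 1:]):
            assert b <= a + 1e-6

    def test_convex_mode_matches_reference(self):
        """Convex-family objective agrees with an independent implementation."""
        rng = np.random.default_rng(11)
        A = rng.normal(size=(20, 6))
        Omega_true = np.eye(20) * 2.0
        Sigma = np.linalg.inv(Omega_true + 0.0) + 0.05 * A @ A.T
        _, S = sample_gaussian(0.5 * (Sigma + Sigma.T), n=80, seed=12)
        lam1, lam2 = 0.05, 0.2
        cfg = PenaltyConfig(family="convex", lam1=lam1, lam2=lam2)
        est = fit_lvggm(S, cfg, ADMMConfig(max_iter=4000, tol_primal=1e-9, tol_change=1e-10))
        Om_ref, L_ref = solve_convex_lvggm(S.S, lam1, lam2)
        f_pkg = objective(S, est.Omega, est.L, cfg)
        f_ref = objective(S, Om_ref, L_ref, cfg)
        assert f_pkg == pytest.approx(f_ref, abs=1e-5)


class TestContractionMatrix:
    @pytest.mark.parametrize("p", [1, 3])
    def test_smallest_eigenvalue(self, p):
        H = contraction_matrix(p)
        assert np.linalg.eigvalsh(H)[0] == pytest.approx((2 - math.sqrt(3)) / 2, abs=1e-12)

    def test_p1_spectrum(self):
        w = np.sort(np.linalg.eigvalsh(contraction_matrix(1)))
        expected = np.sort([(2 - math.sqrt(3)) / 2, 1.0, 1.0, (2 + math.sqrt(3)) / 2])
        np.testing.assert_allclose(w, expected, atol=1e-12)

    def test_kronecker_multiplicity(self):
        w1 = np.sort(np.linalg.eigvalsh(contraction_matrix(1)))
        w3 = np.sort(np.linalg.eigvalsh(contraction_matrix(3)))
        np.testing.assert_allclose(w3, np.repeat(w1, 3), atol=1e-12)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            contraction_matrix(0)
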