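"""Coordinate-descent solver, KKT residuals and Gram diagnostics.

The independent oracle throughout is a bound-constrained quasi-Newton
minimizer (L-BFGS-B) of the same objective: smooth on the non-negative
orthant (where the l1 term is linear), or on the positive/negative split
for signed problems.
"""

import numpy as np
import pytest
from scipy import optimize

from csde import (Dictionary, EmpiricalMoments, PenaltySpec,
                  closed_form_orthonormal, diagnostics, fit, fit_density,
                  kkt_check, objective)
from csde.weights import WeightVector


def wv(omega):
    omega = np.asarray(omega, dtype=float)
    return WeightVector(omega=omega, omega_tilde=omega.copy())


def qp_oracle_nonneg(b, gram, omega, c):
    """Minimize -2 b'x + x'(Psi + cI)x + 2 omega'x over x >= 0."""
    W = b.size
    A = gram + c * np.eye(W)

    def f(x):
        return -2.0 * b @ x + x @ A @ x + 2.0 * omega @ x

    def g(x):
        return -2.0 * b + 2.0 * A @ x + 2.0 * omega

    res = optimize.minimize(f, np.zeros(W), jac=g, method="L-BFGS-B",
                            bounds=[(0.0, None)] * W,
                            options={"ftol": 1e-16, "gtol": 1e-12,
                                     "maxiter": 20_000})
    return res.x


def random_problem(rng, W):
    M = rng.normal(size=(W, W + 3))
    gram = M @ M.T / (W + 3)
    gram += 0.05 * np.eye(W)  # keep the oracle well-posed
    b = rng.uniform(0.0, 1.0, size=W)
    omega = rng.uniform(0.01, 0.3, size=W)
    c = float(rng.uniform(0.0, 0.3))
    return b, gram, omega, c


class TestObjective:
    def test_zero_vector_gives_zero(self):
        m = EmpiricalMoments(b=np.array([0.3, 0.7]), n=10)
        val = objective(np.zeros(2), m, np.eye(2), wv([0.1, 0.1]), 0.5)
        assert val == 0.0

    def test_hand_evaluated_scalar_case(self):
        # -2*0.5*0.4 + 0.4^2*1 + 2*0.1*0.4 = -0.16
        m = EmpiricalMoments(b=np.array([0.5]), n=10)
        val = objective(np.array([0.4]), m, np.array([[1.0]]), wv([0.1]), 0.0)
        assert val == pytest.approx(-0.16, abs=1e-14)

    def test_ridge_term_additivity(self, rng):
        beta = rng.uniform(0, 1, 4)
        m = EmpiricalMoments(b=rng.uniform(0, 1, 4), n=10)
        gram = np.eye(4)
        base = objective(beta, m, gram, wv(np.full(4, 0.1)), 0.0)
        with_c = objective(beta, m, gram, wv(np.full(4, 0.1)), 0.25)
        assert with_c - base == pytest.approx(0.25 * beta @ beta, abs=1e-12)


class TestClosedFormOrthonormal:
    @pytest.mark.parametrize("bt, omega, c, expected", [
        (0.5, 0.1, 0.0, 0.4),
        (0.5, 0.1, 0.25, 0.32),
        (0.05, 0.1, 0.7, 0.0),
        (-0.5, 0.1, 0.0, -0.4),
        (0.0, 0.1, 0.0, 0.0),
    ])
    def test_soft_threshold_values(self, bt, omega, c, expected):
        out = closed_form_orthonormal(np.array([bt]), wv([omega]), c)
        assert out[0] == pytest.approx(expected, abs=1e-14)


class TestFit:
    def test_subthreshold_signal_zeroed_in_one_sweep(self):
        m = EmpiricalMoments(b=np.array([0.05, 0.08]), n=10)
        res = fit(m, np.eye(2), wv([0.1, 0.1]), 0.0)
        assert np.all(res.beta_hat == 0.0)
        assert res.n_iter == 1
        assert res.converged

    def test_matches_orthonormal_closed_form(self, rng):
        b = rng.uniform(-1, 1, 12)
        omega = rng.uniform(0.02, 0.4, 12)
        c = 0.15
        m = EmpiricalMoments(b=b, n=50)
        res = fit(m, np.eye(12), wv(omega), c, nonneg=False, tol=1e-12)
        expected = closed_form_orthonormal(b, wv(omega), c)
        assert np.allclose(res.beta_hat, expected, atol=1e-10)

    def test_two_component_hand_solution(self):
        m = EmpiricalMoments(b=np.array([0.5, 0.05]), n=10)
        res = fit(m, np.eye(2), wv([0.1, 0.1]), 0.1)
        assert res.beta_hat[0] == pytest.approx(0.4 / 1.1, abs=1e-10)
        assert res.beta_hat[1] == 0.0

    def test_agrees_with_qp_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            W = int(rng.integers(2, 21))
            b, gram, omega, c = random_problem(rng, W)
            m = EmpiricalMoments(b=b, n=100)
            res = fit(m, gram, wv(omega), c, tol=1e-10, max_iter=50_000)
            ref = qp_oracle_nonneg(b, gram, omega, c)
            assert np.max(np.abs(res.beta_hat - ref)) < 1e-6

    def test_plain_nonneg_lasso_special_case(self):
        # c=0 with uniform weights reduces to a non-negative Lasso
        rng = np.random.default_rng(3)
        b, gram, _, _ = random_problem(rng, 8)
        omega = np.full(8, 0.12)
        m = EmpiricalMoments(b=b, n=100)
        res = fit(m, gram, wv(omega), 0.0, tol=1e-10, max_iter=50_000)
        ref = qp_oracle_nonneg(b, gram, omega, 0.0)
        assert np.max(np.abs(res.beta_hat - ref)) < 1e-6

    def test_objective_non_increasing_per_sweep(self, rng):
        b, gram, omega, c = random_problem(rng, 10)
        m = EmpiricalMoments(b=b, n=100)
        res = fit(m, gram, wv(omega), c, debug=True)
        trace = res.objective_trace
        assert trace.size >= 1
        assert np.all(np.diff(trace) <= 1e-10)

    def test_penalty_scaling_homogeneity(self, rng):
        # scaling b, Psi, omega and c by the same s > 0 leaves the
        # minimizer unchanged (the objective is scaled by s)
        b, gram, omega, c = random_problem(rng, 6)
        s = 3.7
        res1 = fit(EmpiricalMoments(b=b, n=10), gram, wv(omega), c, tol=1e-12)
        res2 = fit(EmpiricalMoments(b=s * b, n=10), s * gram, wv(s * omega),
                   s * c, tol=1e-12)
        assert np.allclose(res1.beta_hat, res2.beta_hat, atol=1e-8)

    def test_max_iter_flag_without_exception(self):
        rng = np.random.default_rng(5)
        b, gram, omega, c = random_problem(rng, 10)
        m = EmpiricalMoments(b=b, n=100)
        res = fit(m, gram, wv(omega * 0.0), 0.0, tol=1e-14, max_iter=2)
        assert not res.converged


class TestKKT:
    def test_zero_solution_zero_violation(self):
        m = EmpiricalMoments(b=np.array([0.05, -0.02]), n=10)
        res = fit(m, np.eye(2), wv([0.1, 0.1]), 0.0, nonneg=False)
        assert res.beta_hat.tolist() == [0.0, 0.0]
        assert res.kkt_max_violation == 0.0

    @pytest.mark.parametrize("nonneg", [True, False])
    def test_converged_fit_satisfies_kkt(self, nonneg):
        rng = np.random.default_rng(11)
        for _ in range(10):
            b, gram, omega, c = random_problem(rng, 12)
            m = EmpiricalMoments(b=b, n=100)
            res = fit(m, gram, wv(omega), c, nonneg=nonneg, tol=1e-8,
                      max_iter=100_000)
            assert res.converged
            assert res.kkt_max_violation <= 1e-6

    def test_perturbed_active_coordinate_violates(self):
        rng = np.random.default_rng(13)
        b, gram, omega, c = random_problem(rng, 8)
        m = EmpiricalMoments(b=b, n=100)
        res = fit(m, gram, wv(omega), c, tol=1e-10, max_iter=50_000)
        active = res.support
        if active.size == 0:
            pytest.skip("no active coordinate in this draw")
        k = active[0]
        res.beta_hat[k] += 0.01
        viol, _ = kkt_check(res, m, gram, wv(omega), c)
        assert viol >= 0.01 * (gram[k, k] + c) - 1e-6

    def test_nonneg_inactive_condition_is_one_sided(self):
        # strongly negative gradient is feasible at the boundary in
        # non-negative mode but violates the signed stationarity
        m = EmpiricalMoments(b=np.array([-5.0]), n=10)
        res = fit(m, np.eye(1), wv([0.1]), 0.0)
        v_nn, _ = kkt_check(res, m, np.eye(1), wv([0.1]), 0.0, nonneg=True)
        v_sg, _ = kkt_check(res, m, np.eye(1), wv([0.1]), 0.0, nonneg=False)
        assert v_nn == 0.0
        assert v_sg > 1.0


class TestDiagnostics:
    def test_identity_gram(self):
        out = diagnostics(np.eye(4), [0, 2])
        assert out == {"rho_max": 0.0, "rho_star": 0.0, "lambda_min": 1.0}

    def test_two_by_two_hand_case(self):
        gram = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = diagnostics(gram, [0])
        assert out["rho_max"] == pytest.approx(0.5)
        assert out["rho_star"] == pytest.approx(0.5)
        assert out["lambda_min"] == pytest.approx(0.5)

    def test_empty_support(self):
        out = diagnostics(np.eye(3), [])
        assert out["rho_max"] is None and out["rho_star"] is None
        assert out["lambda_min"] == pytest.approx(1.0)

    def test_gaussian_dictionary_vs_dense_eigensolver(self):
        from scipy.linalg import eigvalsh

        from csde import gaussian_scenario
        gram = gaussian_scenario(81).dict_true.gram
        out = diagnostics(gram, list(range(81)))
        assert out["lambda_min"] == pytest.approx(eigvalsh(gram)[0], abs=1e-8)
        # brute-force coherence oracle
        dnorm = np.sqrt(np.diag(gram))
        rho = gram / np.outer(dnorm, dnorm)
        brute_max = max(abs(rho[i, j]) for i in range(81) for j in range(81)
                        if i != j)
        assert out["rho_max"] == pytest.approx(brute_max, abs=1e-12)


class TestFitDensity:
    def test_one_call_matches_manual_pipeline(self, small_gaussian_dict, rng):
        x = rng.normal(1.0, 1.0, size=60)
        spec = PenaltySpec(lam1=0.05, c=0.02, mode="csde",
                           weight_scale_mode="fixed_lam1")
        res = fit_density(x, small_gaussian_dict, spec)
        from csde import compute_weights
        m = EmpiricalMoments.from_samples(small_gaussian_dict, x)
        w = compute_weights(spec, small_gaussian_dict.sup_norms,
                            small_gaussian_dict.W, m.n)
        ref = fit(m, small_gaussian_dict.gram, w, 0.02)
        assert np.allclose(res.beta_hat, ref.beta_hat, atol=1e-12)

    def test_spades_mode_has_no_ridge(self, small_gaussian_dict, rng):
        x = rng.normal(1.0, 1.0, size=60)
        a = fit_density(x, small_gaussian_dict,
                        PenaltySpec(lam1=0.01, c=5.0, mode="spades"))
        b = fit_density(x, small_gaussian_dict,
                        PenaltySpec(lam1=0.01, c=0.0, mode="spades"))
        assert np.allclose(a.beta_hat, b.beta_hat, atol=1e-12)
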