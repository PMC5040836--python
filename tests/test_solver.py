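"""Solver machinery: nonlinearities, multipliers, Newton steps, extraction.

The two Newton updates are checked against independently transcribed
implementations of the printed learning rules (the oracles below follow
the equations term by term and share no code with the solver).
"""

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss

from icaref import (
    MultichannelSignal,
    SolverConfig,
    SourceSet,
    estimate_c_sign,
    run_extraction,
    run_on_whitened,
    standardize,
)
from icaref.preprocess import center_and_whiten
from icaref.reference import as_reference, build_sign_reference
from icaref.solver import (
    LagrangeState,
    closeness,
    closeness_gradient,
    gaussian_logcosh_expectation,
    init_separating_vector,
    newton_step_baseline,
    newton_step_fast,
    nonlinearity_logcosh,
    nonlinearity_quartic,
    update_lambda,
    update_mu,
)

# ---------------------------------------------------------------------------
# independently transcribed one-step oracles


def _gauss_EF(a: float) -> float:
    # E{(1/a) log cosh(a v)} for standard normal v by Gauss-Hermite quadrature
    nodes, weights = hermegauss(201)
    return float(np.sum(weights * np.log(np.cosh(a * nodes)) / a) / np.sqrt(2 * np.pi))


def oracle_fast_step(w, x, r, rho, eta, mu, a, xi):
    T = x.shape[1]
    y = w @ x
    f = np.tanh(a * y)
    fp = a * (1.0 - np.tanh(a * y) ** 2)
    grad_g = 2.0 * (x @ (y - r)) / T
    l = rho * (x @ f) / T + mu * grad_g
    delta = rho * np.mean(fp) + mu * 2.0
    wn = w - eta * l / delta
    return wn / np.linalg.norm(wn)


def oracle_baseline_step(w, x, Rinv, r, rho, eta, mu, lam, a, xi):
    T = x.shape[1]
    y = w @ x
    F = np.log(np.cosh(a * y)) / a
    f = np.tanh(a * y)
    fp = a * (1.0 - np.tanh(a * y) ** 2)
    rho_hat = 2.0 * rho * (np.mean(F) - _gauss_EF(a))
    grad_g = 2.0 * (x @ (y - r)) / T
    Ey2 = np.mean(y**2)
    Exy = (x @ y) / T
    l = rho_hat * (x @ f) / T - mu * grad_g - 4.0 * lam * (Ey2 - 1.0) * Exy
    delta = rho_hat * np.mean(fp) - mu * 2.0 - 8.0 * lam
    wn = w - eta * (Rinv @ l) / delta
    return wn / np.linalg.norm(wn)


@pytest.fixture()
def small_fixture(rng):
    x = rng.normal(size=(2, 40))
    x = x - x.mean(axis=1, keepdims=True)
    r = standardize(rng.normal(size=40))
    w = rng.normal(size=2)
    return x, r, w / np.linalg.norm(w)


# ---------------------------------------------------------------------------
# nonlinearities


class TestNonlinearities:
    def test_logcosh_at_zero(self):
        F, f, fp = nonlinearity_logcosh(np.array([0.0]), a=2.0)
        assert F[0] == 0.0 and f[0] == 0.0 and fp[0] == 2.0

    def test_logcosh_at_one(self):
        F, f, fp = nonlinearity_logcosh(np.array([1.0]), a=1.0)
        assert F[0] == pytest.approx(0.4337808304830271, abs=1e-14)
        assert f[0] == pytest.approx(np.tanh(1.0), abs=1e-14)

    def test_logcosh_overflow_safe(self):
        F, f, fp = nonlinearity_logcosh(np.array([700.0, -700.0]), a=1.0)
        assert np.all(np.isfinite(F))
        assert F[0] == pytest.approx(700.0 - np.log(2.0), rel=1e-12)

    def test_quartic_values_and_symmetry(self, rng):
        F, f, fp = nonlinearity_quartic(np.array([1.0]), b=4.0)
        assert (F[0], f[0], fp[0]) == (1.0, 4.0, 12.0)
        y = rng.normal(size=50)
        _, f1, fp1 = nonlinearity_quartic(y, b=2.0)
        _, f2, fp2 = nonlinearity_quartic(-y, b=2.0)
        assert np.allclose(f1, -f2)  # f odd
        assert np.allclose(fp1, fp2)  # f' even

    def test_gaussian_expectation_matches_quadrature_oracle(self):
        # hermegauss converges slowly on the |y|-like tails, hence 1e-9
        for a in (1.0, 2.0):
            assert gaussian_logcosh_expectation(a) == pytest.approx(_gauss_EF(a), abs=1e-9)


# ---------------------------------------------------------------------------
# closeness and its gradient


class TestCloseness:
    def test_identical_signals(self, rng):
        y = standardize(rng.normal(size=100))
        eps, g = closeness(y, as_reference(y), xi=0.3)
        assert eps == pytest.approx(0.0, abs=1e-12)
        assert g == pytest.approx(-0.3, abs=1e-12)

    def test_antipodal_signals(self, rng):
        y = standardize(rng.normal(size=100))
        eps, _ = closeness(-y, as_reference(y), xi=0.0)
        assert eps == pytest.approx(4.0, abs=1e-9)

    def test_independent_signals_near_two(self, rng):
        y = standardize(rng.normal(size=100_000))
        r = as_reference(rng.normal(size=100_000))
        eps, _ = closeness(y, r, xi=0.0)
        assert eps == pytest.approx(2.0, abs=0.05)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            closeness(np.ones(5), as_reference(rng.normal(size=6)), 0.0)

    def test_gradient_zero_when_matched(self, rng):
        x = rng.normal(size=(2, 50))
        y = x[0]
        assert np.allclose(closeness_gradient(x, y, y), 0.0)

    def test_gradient_matches_finite_differences(self, rng):
        x = rng.normal(size=(3, 50))
        r = standardize(rng.normal(size=50))
        w = rng.normal(size=3)
        grad = closeness_gradient(x, w @ x, r)
        h = 1e-6
        fd = np.empty(3)
        for i in range(3):
            wp, wm = w.copy(), w.copy()
            wp[i] += h
            wm[i] -= h
            fd[i] = (np.mean((wp @ x - r) ** 2) - np.mean((wm @ x - r) ** 2)) / (2 * h)
        assert np.allclose(grad, fd, atol=1e-6)


# ---------------------------------------------------------------------------
# initialization and multiplier updates


class TestInitialization:
    def test_recovers_basis_vector_for_exact_channel(self, rng):
        x = rng.normal(size=(3, 4000))
        x = x - x.mean(axis=1, keepdims=True)
        res = center_and_whiten(MultichannelSignal(x))
        xw = res.whitened.data
        r = as_reference(xw[1])
        w0 = init_separating_vector(xw, r)
        assert np.allclose(np.abs(w0), [0, 1, 0], atol=1e-6)

    def test_scale_invariance(self, rng):
        x = rng.normal(size=(2, 300))
        r = standardize(rng.normal(size=300)) + 0.5 * x[0]
        w1 = init_separating_vector(x, as_reference(r))
        w2 = init_separating_vector(x, as_reference(10 * r))
        assert np.allclose(w1, w2, atol=1e-12)

    def test_orthogonal_reference_rejected(self):
        x = np.vstack([np.ones(64), np.tile([1.0, -1.0], 32)])
        r = np.tile([1.0, 1.0, -1.0, -1.0], 16)  # orthogonal to both rows
        with pytest.raises(ValueError, match="orthogonal"):
            init_separating_vector(x, r)


@pytest.mark.parametrize(
    "mu, gamma, g, expected",
    [(0.0, 1.0, -1.0, 0.0), (1.0, 1.0, 0.5, 1.5), (1.0, 1.0, -2.0, 0.0)],
)
def test_update_mu(mu, gamma, g, expected):
    assert update_mu(mu, gamma, g) == expected


def test_update_lambda_and_whitened_stationarity(rng):
    assert update_lambda(0.0, 1.0, 0.0) == 0.0
    assert update_lambda(1.0, 1.0, 0.2) == pytest.approx(1.2)
    # on whitened data any unit w gives E{y^2} = 1, so lambda is stationary
    res = center_and_whiten(MultichannelSignal(rng.normal(size=(3, 5000)) * [[1], [3], [0.2]]))
    w = rng.normal(size=3)
    w /= np.linalg.norm(w)
    h = np.mean((w @ res.whitened.data) ** 2) - 1.0
    assert update_lambda(0.5, 1.0, h) == pytest.approx(0.5, abs=1e-6)


# ---------------------------------------------------------------------------
# Newton steps vs transcribed oracles


class TestNewtonSteps:
    def test_fast_step_matches_oracle(self, small_fixture):
        x, r, w = small_fixture
        cfg = SolverConfig(variant="fast", a=1.3, rho=0.8, eta=0.9)
        for mu in (0.0, 0.7):
            state = LagrangeState(w=w, mu=mu)
            out = newton_step_fast(state, x, r, cfg)
            expected = oracle_fast_step(w, x, r, cfg.rho, cfg.eta, mu, cfg.a, xi=0.5)
            assert np.linalg.norm(out.w - expected) < 1e-10

    def test_baseline_step_matches_oracle(self, small_fixture):
        x, r, w = small_fixture
        Rinv = np.linalg.inv(x @ x.T / x.shape[1])
        cfg = SolverConfig(variant="baseline", a=1.0, rho=1.2, eta=0.8)
        state = LagrangeState(w=w, mu=0.4, lam=0.3)
        out = newton_step_baseline(state, x, Rinv, r, cfg)
        expected = oracle_baseline_step(
            w, x, Rinv, r, cfg.rho, cfg.eta, 0.4, 0.3, cfg.a, xi=0.5
        )
        assert np.linalg.norm(out.w - expected) < 1e-10

    def test_mu_zero_reduces_to_negentropy_descent(self, small_fixture):
        x, r, w = small_fixture
        cfg = SolverConfig()
        out = newton_step_fast(LagrangeState(w=w, mu=0.0), x, r, cfg)
        # with mu = 0 the reference must not influence the step
        r2 = standardize(np.cos(np.arange(40)))
        out2 = newton_step_fast(LagrangeState(w=w, mu=0.0), x, r2, cfg)
        assert np.allclose(out.w, out2.w, atol=1e-14)

    def test_variants_coincide_on_whitened_super_gaussian(self, rng):
        # with rho set to |rho_hat|, the fast step reproduces the baseline
        # step on whitened data (R^{-1} = I, rho_hat < 0 for super-Gaussian y)
        lap = standardize(rng.laplace(size=4000))
        gau = standardize(rng.standard_normal(4000))
        res = center_and_whiten(MultichannelSignal(np.vstack([lap, gau])))
        xw = res.whitened.data
        r = build_sign_reference(lap).values
        w = np.array([0.9, np.sqrt(1 - 0.81)])
        y = w @ xw
        F, _, _ = nonlinearity_logcosh(y)
        rho_hat = 2.0 * (np.mean(F) - gaussian_logcosh_expectation(1.0))
        assert rho_hat < 0
        mu = 0.25
        fast_cfg = SolverConfig(rho=abs(rho_hat))
        out_fast = newton_step_fast(LagrangeState(w=w, mu=mu), xw, r, fast_cfg)
        Rinv = np.linalg.inv(xw @ xw.T / xw.shape[1])
        out_base = newton_step_baseline(
            LagrangeState(w=w, mu=mu, lam=0.0), xw, Rinv, r, SolverConfig(variant="baseline")
        )
        assert min(
            np.linalg.norm(out_fast.w - out_base.w), np.linalg.norm(out_fast.w + out_base.w)
        ) < 1e-3

    def test_stationary_at_converged_optimum(self, rng):
        lap = standardize(rng.laplace(size=5000))
        gau = standardize(rng.standard_normal(5000))
        res = center_and_whiten(MultichannelSignal(np.vstack([lap, gau])))
        xw = res.whitened.data
        ref = build_sign_reference(lap)
        result = run_on_whitened(xw, ref, SolverConfig())
        extra = newton_step_fast(LagrangeState(w=result.w, mu=0.0), xw, ref.values, SolverConfig())
        assert extra.last_step_norm < 1e-3

    def test_collinear_force_leaves_direction_unchanged(self):
        # if l is parallel to w, normalization absorbs the step entirely
        x = np.vstack([np.tile([1.0, -1.0], 20), np.tile([1.0, 1.0, -1.0, -1.0], 10)])
        w = np.array([1.0, 0.0])
        r = np.zeros(40)
        out = newton_step_fast(LagrangeState(w=w, mu=0.0), x, r, SolverConfig())
        assert min(np.linalg.norm(out.w - w), np.linalg.norm(out.w + w)) < 1e-12


# ---------------------------------------------------------------------------
# kurtosis-sign analysis


class TestSignAnalysis:
    def test_laplacian_is_super_gaussian(self, rng):
        y = standardize(rng.laplace(size=100_000))
        est = estimate_c_sign(y)
        assert est.c_exact < 0 and est.sign == -1
        assert est.c_taylor < 0

    def test_uniform_exposes_taylor_limits(self, rng):
        y = rng.uniform(-np.sqrt(3), np.sqrt(3), size=200_000)
        est = estimate_c_sign(y)
        # E{y^4} = 9/5 for unit-variance uniform -> Taylor surrogate -0.8,
        # yet the exact statistic is positive (sub-Gaussian)
        assert est.c_taylor == pytest.approx(-0.8, abs=0.02)
        assert est.c_exact > 0

    def test_gaussian_gives_zero_by_stein_identity(self, rng):
        y = standardize(rng.standard_normal(100_000))
        est = estimate_c_sign(y)
        assert abs(est.c_exact) < 0.02


# ---------------------------------------------------------------------------
# full extraction runs


class TestRunExtraction:
    def test_recovers_laplacian_from_identity_mixture(self, rng):
        lap = standardize(rng.laplace(size=2000))
        gau = standardize(rng.standard_normal(2000))
        src = SourceSet(MultichannelSignal(np.vstack([lap, gau])), labels=["lap", "gau"])
        ref = build_sign_reference(lap)
        result = run_extraction(src.signals, ref, SolverConfig())
        assert result.converged
        assert abs(np.corrcoef(result.y, lap)[0, 1]) > 0.999

    def test_exact_reference_converges_in_few_iterations(self, benchmark_case):
        x = benchmark_case["mixture"]
        r = as_reference(benchmark_case["sources"].row("fecg"))
        result = run_extraction(x, r, SolverConfig(varsigma=1e-6))
        assert result.converged
        assert result.iterations <= 5

    def test_invariants_along_the_run(self, benchmark_case, whitened_benchmark):
        xw = whitened_benchmark.whitened.data
        ref = build_sign_reference(benchmark_case["sources"].row("mecg"))
        result = run_on_whitened(xw, ref, SolverConfig())
        assert abs(np.linalg.norm(result.w) - 1.0) < 1e-12
        assert np.all(result.mu_trajectory >= 0)
        assert abs((result.w @ xw).var() - 1.0) < 1e-6
        # output sign aligned with the reference
        assert np.corrcoef(result.y, ref.values)[0, 1] >= 0

    def test_nonconvergence_is_flagged_not_raised(self, benchmark_case):
        ref = build_sign_reference(benchmark_case["sources"].row("fecg"))
        result = run_extraction(benchmark_case["mixture"], ref, SolverConfig(max_iter=2))
        assert result.converged is False
        assert result.iterations == 2

    def test_random_init_is_seeded(self, benchmark_case):
        ref = build_sign_reference(benchmark_case["sources"].row("fecg"))
        cfg = SolverConfig(init="random", seed=11)
        a = run_extraction(benchmark_case["mixture"], ref, cfg)
        b = run_extraction(benchmark_case["mixture"], ref, cfg)
        assert np.array_equal(a.w, b.w)

    def test_degraded_reference_degrades_median_ipi(self):
        # coarse sanity: more reference noise never helps (median IPI over
        # a small seed grid is non-decreasing along the noise grid)
        from icaref import benchmark_mixing_matrix, benchmark_sources, mix
        from icaref.evaluate import global_vector, ipi

        spec = benchmark_mixing_matrix()
        medians = []
        for noise in (0.0, 2.0, 8.0):
            vals = []
            for seed in range(1, 6):
                src = benchmark_sources(seed)
                x = mix(src, spec)
                rng = np.random.default_rng(1000 + seed)
                noisy = src.row("fecg") + noise * rng.standard_normal(src.signals.n_samples)
                ref = build_sign_reference(noisy)
                wres = center_and_whiten(x)
                res = run_on_whitened(wres.whitened.data, ref, SolverConfig())
                vals.append(ipi(global_vector(res.w, wres.whitening_matrix, spec.matrix)))
            medians.append(np.median(vals))
        assert medians[0] <= medians[1] + 1e-6 <= medians[2] + 2e-6
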