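import numpy as np
import pytest
from scipy.stats import norm

from qreslife import (
    EstimatorControl,
    GammaVector,
    SmoothingConfig,
    build_design_row,
    fit_censoring_km,
    induced_smoothing_estimate,
    nonsmooth_estimate,
    nonsmooth_estimating_function,
    simulate_setup2,
    smoothed_estimating_function,
    fractional_polynomial_basis,
    true_coefficients,
)
from qreslife.censoring import evaluate_G
from qreslife.data import StudyData, SubjectRecord


def brute_force_ef(gamma, data, tau, basis, G, H=None):
    """Literal double-loop transcription of the estimating function.

    With H=None the indicator version; otherwise the normal-CDF smoothed
    version.  Intentionally naive: the independent oracle for the
    vectorized implementation.
    """
    gamma = np.asarray(gamma, float)
    d = gamma.size
    total = np.zeros(d)
    for s in data.subjects:
        for j, t_j in enumerate(data.visit_schedule):
            if not s.visit_attended[j] or not s.observed_time > t_j:
                continue
            U = build_design_row(s, j, basis, data.visit_schedule)
            r = np.log(s.observed_time - t_j)
            ratio = 0.0
            if s.event_indicator == 1:
                g_y = evaluate_G(G, s.observed_time)
                if g_y > 0:
                    ratio = evaluate_G(G, t_j) / g_y
            if H is None:
                ind = float(r <= gamma @ U)
            else:
                ind = norm.cdf((gamma @ U - r) / np.sqrt(U @ H @ U))
            total += U * (ind * ratio - tau)
    return total / data.n


def intercept_only_data(Y, delta=None, t0=0.05):
    delta = [1] * len(Y) if delta is None else delta
    subjects = [
        SubjectRecord(str(i), y, d, [], [1], np.empty((1, 0)))
        for i, (y, d) in enumerate(zip(Y, delta))
    ]
    return StudyData(subjects, [t0])


INTERCEPT_BASIS = fractional_polynomial_basis(["1"])


class TestNonsmoothEstimatingFunction:
    def test_censored_subject_contributes_only_tau_term(self, fp_basis):
        s = SubjectRecord("s", 1.0, 0, [0.5], [1, 1], [[0.2], [0.1]])
        data = StudyData([s], [0.25, 0.5])
        G = fit_censoring_km(data)
        gamma = np.zeros(12)
        got = nonsmooth_estimating_function(gamma, data, 0.3, fp_basis, G)
        expected = -(0.3) * sum(
            build_design_row(s, j, fp_basis, data.visit_schedule) for j in (0, 1)
        )
        np.testing.assert_allclose(got, expected)

    def test_indicator_saturation_gives_one_minus_tau(self):
        data = intercept_only_data([2.0])
        G = fit_censoring_km(data)
        got = nonsmooth_estimating_function([50.0], data, 0.25,
                                            INTERCEPT_BASIS, G)
        np.testing.assert_allclose(got, [0.75])

    def test_matches_brute_force_loop(self, toy_data, fp_basis):
        G = fit_censoring_km(toy_data)
        rng = np.random.default_rng(4)
        for _ in range(5):
            gamma = rng.normal(size=12)
            np.testing.assert_allclose(
                nonsmooth_estimating_function(gamma, toy_data, 0.4, fp_basis, G),
                brute_force_ef(gamma, toy_data, 0.4, fp_basis, G),
                atol=1e-12,
            )

    def test_tau_out_of_range_rejected(self, toy_data, fp_basis):
        G = fit_censoring_km(toy_data)
        with pytest.raises(ValueError, match="tau"):
            nonsmooth_estimating_function(np.zeros(12), toy_data, 1.2, fp_basis, G)


class TestSmoothedEstimatingFunction:
    def test_matches_brute_force_loop(self, toy_data, fp_basis):
        G = fit_censoring_km(toy_data)
        rng = np.random.default_rng(11)
        H = np.diag(rng.uniform(0.01, 0.1, 12))
        cfg = SmoothingConfig(H=H)
        for _ in range(3):
            gamma = rng.normal(size=12)
            np.testing.assert_allclose(
                smoothed_estimating_function(gamma, toy_data, 0.4, fp_basis, G, cfg),
                brute_force_ef(gamma, toy_data, 0.4, fp_basis, G, H=H),
                atol=1e-12,
            )

    def test_vanishing_bandwidth_recovers_indicator(self, toy_data, fp_basis):
        G = fit_censoring_km(toy_data)
        rng = np.random.default_rng(5)
        gamma = rng.normal(size=12)  # residual ties have probability zero
        tiny = SmoothingConfig(H=1e-12 * np.eye(12))
        np.testing.assert_allclose(
            smoothed_estimating_function(gamma, toy_data, 0.4, fp_basis, G, tiny),
            nonsmooth_estimating_function(gamma, toy_data, 0.4, fp_basis, G),
            atol=1e-9,
        )

    def test_single_term_root_closed_form(self):
        # root of Phi((gamma - r)/sigma) - tau = 0 is r + sigma Phi^-1(tau)
        data = intercept_only_data([2.0])
        tau, h = 0.3, 0.04
        fit = induced_smoothing_estimate(
            data, tau, INTERCEPT_BASIS,
            smoothing=SmoothingConfig(H=np.array([[h]])),
            control=EstimatorControl(tol=1e-12, initializer="zero"),
        )
        expected = np.log(2.0 - 0.05) + np.sqrt(h) * norm.ppf(tau)
        assert fit.gamma.values[0] == pytest.approx(expected, abs=1e-8)

    def test_monotone_in_gamma_component(self, toy_data, fp_basis):
        # the smoothed indicator preserves monotonicity of each contribution
        G = fit_censoring_km(toy_data)
        grid = np.linspace(-3, 3, 21)
        vals = [
            smoothed_estimating_function(
                np.r_[g, np.zeros(11)], toy_data, 0.4, fp_basis, G)[0]
            for g in grid
        ]
        assert np.all(np.diff(vals) >= -1e-12)


class TestNonsmoothEstimate:
    def test_intercept_only_median(self):
        Y = np.array([0.5, 1.0, 2.0, 3.0, 5.0])
        data = intercept_only_data(Y)
        fit = nonsmooth_estimate(data, 0.5, INTERCEPT_BASIS)
        assert fit.gamma.values[0] == pytest.approx(np.log(2.0 - 0.05), abs=1e-8)

    def test_intercept_only_quartile_matches_grid_search(self):
        Y = np.array([0.3, 0.7, 1.1, 1.9, 2.5, 3.3, 4.1])
        data = intercept_only_data(Y)
        tau = 0.25
        fit = nonsmooth_estimate(data, tau, INTERCEPT_BASIS)
        r = np.log(Y - 0.05)
        grid = np.linspace(r.min() - 0.5, r.max() + 0.5, 20001)
        # for M -> inf the objective with its two pseudo-observations reduces
        # to the standard check loss sum rho_tau(r - g)
        loss = [np.sum((r - g) * (tau - (r < g))) for g in grid]
        g_star = grid[int(np.argmin(loss))]
        assert fit.gamma.values[0] == pytest.approx(g_star, abs=1e-3)

    def test_lp_matches_dense_grid_on_two_dim_instance(self):
        rng = np.random.default_rng(13)
        Y = rng.uniform(0.5, 4.0, 9)
        W = rng.normal(size=9)
        subjects = [
            SubjectRecord(str(i), Y[i], 1, [W[i]], [1], np.empty((1, 0)))
            for i in range(9)
        ]
        data = StudyData(subjects, [0.1])
        basis = INTERCEPT_BASIS
        tau = 0.4
        fit = nonsmooth_estimate(data, tau, basis)
        r = np.log(Y - 0.1)
        X = np.column_stack([np.ones(9), W])

        def objective(g):
            resid = r - X @ g
            return np.sum(np.where(resid >= 0, tau, 1 - tau) * np.abs(resid))

        g0 = np.linspace(fit.gamma.values[0] - 0.5, fit.gamma.values[0] + 0.5, 81)
        g1 = np.linspace(fit.gamma.values[1] - 0.5, fit.gamma.values[1] + 0.5, 81)
        best = min(objective(np.array([a, b])) for a in g0 for b in g1)
        assert objective(fit.gamma.values) <= best + 1e-9

    def test_subgradient_condition_at_lp_solution(self, fp_basis):
        sim = simulate_setup2(150, tau=0.5, seed=77)
        fit = nonsmooth_estimate(sim.data, 0.5, fp_basis)
        ef = nonsmooth_estimating_function(fit.gamma, sim.data, 0.5, fp_basis, fit.G)
        from qreslife.estimators import TermTable

        terms = TermTable(sim.data, fp_basis)
        g_ratio = terms.g_ratio(fit.G)
        resid = terms.r - terms.U @ fit.gamma.values
        active = np.abs(resid) <= 1e-7 * (1 + np.abs(terms.r))
        bound = (np.abs(terms.U[active]) * g_ratio[active, None]).sum(axis=0) / terms.n
        assert np.all(np.abs(ef) <= bound + 1e-8)

    def test_rank_deficient_design_reported(self):
        # a constant time-varying covariate duplicates the intercept block
        subjects = [
            SubjectRecord(str(i), y, 1, [], [1], [[1.0]])
            for i, y in enumerate([0.5, 1.0, 2.0])
        ]
        data = StudyData(subjects, [0.1])
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            nonsmooth_estimate(data, 0.5, INTERCEPT_BASIS)


class TestInducedSmoothingEstimate:
    def test_intercept_only_consistency(self):
        rng = np.random.default_rng(21)
        Y = rng.exponential(1.0, 2000)
        data = intercept_only_data(Y, t0=0.1)
        fit = induced_smoothing_estimate(data, 0.5, INTERCEPT_BASIS)
        assert fit.converged
        # memorylessness: median residual life beyond 0.1 is log 2
        assert fit.gamma.values[0] == pytest.approx(np.log(np.log(2)), abs=0.1)

    def test_root_verified_independently(self, setup2_fit):
        sim, fit = setup2_fit
        S = smoothed_estimating_function(
            fit.gamma, sim.data, fit.tau, fit.basis, fit.G,
            SmoothingConfig(H=fit.H),
        )
        assert np.max(np.abs(S)) <= EstimatorControl().tol

    def test_agrees_with_nonsmooth_within_sampling_error(self, setup2_fit):
        sim, fit = setup2_fit
        from qreslife import estimate_variance

        ns = nonsmooth_estimate(sim.data, fit.tau, fit.basis)
        times = np.array([0.1, 0.2, 0.5, 0.8])
        cf_is = fit.coefficients(times)
        cf_ns = ns.coefficients(times)
        # the two estimators share their limit law: pointwise differences
        # stay within the estimate's own sampling scale
        Sigma = estimate_variance(fit, K=100, seed=99).Sigma
        from qreslife import coefficient_function_se

        se = coefficient_function_se(Sigma, fit.basis, times, p=1, q=1)
        for name in ("alpha0", "alpha1", "beta1"):
            diff = np.abs(cf_is[name].values - cf_ns[name].values)
            assert np.all(diff <= 2.0 * se[name]["se"] + 0.05)

    def test_parameter_recovery_setup2(self):
        # moderate-replication check that both estimators are unbiased under
        # a correctly specified model
        times = np.array([0.1, 0.2, 0.5, 0.8])
        basis = fractional_polynomial_basis()
        reps = {"induced_smooth": [], "nonsmooth": []}
        for rep in range(12):
            sim = simulate_setup2(2000, tau=0.5, seed=1000 + rep)
            for method, fitter in (
                ("induced_smooth", induced_smoothing_estimate),
                ("nonsmooth", nonsmooth_estimate),
            ):
                fit = fitter(sim.data, 0.5, basis)
                cf = fit.coefficients(times)
                reps[method].append(np.stack([
                    cf["alpha0"].values, cf["alpha1"].values, cf["beta1"].values
                ]))
        truth = np.stack(true_coefficients("II", 0.5, times))
        for method, stack in reps.items():
            est = np.stack(stack)
            bias = est.mean(axis=0) - truth
            mcse = est.std(axis=0, ddof=1) / np.sqrt(est.shape[0])
            assert np.all(np.abs(bias) <= 2.5 * mcse + 0.02), method

    def test_nonconvergence_is_flagged_not_silent(self, toy_data, fp_basis):
        # 3 subjects cannot identify 12 parameters; the LP initializer
        # already fails loudly on the rank-deficient design
        with pytest.raises(np.linalg.LinAlgError):
            induced_smoothing_estimate(toy_data, 0.5, fp_basis)
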