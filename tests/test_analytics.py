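import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.stats import beta as beta_dist

from phenoswitch import (
    DomainError,
    InitialComposition,
    RateParameters,
    fano_drug,
    mean_growth,
    mean_surviving_drug,
    moments_growth,
    population_gf,
    script_F_empirical,
    script_F_theory,
    single_cell_gf,
    single_cell_occupancy,
)
from phenoswitch.analytics import drug_matrix, growth_matrix, moment_matrix

from conftest import random_rate_grid


def richardson_derivative(f, x, h=1e-5):
    """Central difference with one Richardson extrapolation step."""
    d1 = (f(x + h) - f(x - h)) / (2 * h)
    d2 = (f(x + h / 2) - f(x - h / 2)) / h
    return (4 * d2 - d1) / 3


def binomial_mixture_moments(params, N0, p0, t):
    """Exact (mean, var) of N for M0 ~ Binomial(N0, p0), by enumeration.

    Independent oracle for the drug-phase Fano closed form: conditions on
    each possible initial split and combines with the law of total variance.
    """
    from scipy.stats import binom

    means, variances, probs = [], [], []
    for M0 in range(N0 + 1):
        ms = moments_growth(params, N0 - M0, M0, [t])
        means.append(ms.mean_N[0])
        variances.append(ms.var_N[0])
        probs.append(binom.pmf(M0, N0, p0))
    means, variances, probs = map(np.asarray, (means, variances, probs))
    mean = float(np.sum(probs * means))
    var = float(np.sum(probs * variances) + np.sum(probs * means**2) - mean**2)
    return mean, var


class TestSingleCellOccupancy:
    def test_initial_condition(self, drug_params):
        occ = single_cell_occupancy(drug_params, 0.2, 0.0)
        assert occ.P_E == pytest.approx(0.8, abs=1e-14)
        assert occ.P_M == pytest.approx(0.2, abs=1e-14)

    def test_decoupled_deaths(self):
        p = RateParameters(0, 0, 0.5, 0.2, 0.0, 0.0)
        occ = single_cell_occupancy(p, 0.3, 2.0)
        assert occ.P_E == pytest.approx(np.exp(-1.0) * 0.7, rel=1e-12)
        assert occ.P_M == pytest.approx(np.exp(-0.4) * 0.3, rel=1e-12)

    def test_expm_oracle(self, drug_params):
        oracle = expm(drug_matrix(drug_params) * 2.0) @ np.array([0.8, 0.2])
        occ = single_cell_occupancy(drug_params, 0.2, 2.0)
        assert occ.P_E == pytest.approx(oracle[0], abs=1e-10)
        assert occ.P_M == pytest.approx(oracle[1], abs=1e-10)

    def test_expm_oracle_random_grid(self):
        # includes the degenerate alpha0 ~ 0 regime via equal death rates
        cases = random_rate_grid(30, seed=10)
        cases.append(RateParameters(0, 0, 0.3, 0.3, 1e-12, 1e-12))
        for p in cases:
            pd = p.without_births()
            for t in (0.5, 3.0):
                oracle = expm(drug_matrix(pd) * t) @ np.array([0.6, 0.4])
                occ = single_cell_occupancy(pd, 0.4, t)
                assert occ.P_E == pytest.approx(oracle[0], abs=1e-10)
                assert occ.P_M == pytest.approx(oracle[1], abs=1e-10)

    def test_probabilities_in_range(self, drug_params):
        for t in np.linspace(0, 30, 40):
            occ = single_cell_occupancy(drug_params, 0.5, t)
            assert 0 <= occ.P_E <= 1 and 0 <= occ.P_M <= 1
            assert occ.P_E + occ.P_M <= 1 + 1e-12

    def test_domain_error(self, drug_params):
        with pytest.raises(DomainError):
            single_cell_occupancy(drug_params, 1.2, 1.0)


class TestSingleCellGF:
    def test_normalization(self, drug_params):
        assert single_cell_gf(1.0, 1.0, drug_params, 0.3, 5.0) == pytest.approx(1.0)

    def test_alive_at_t0(self, drug_params):
        assert single_cell_gf(0.0, 0.0, drug_params, 0.3, 0.0) == pytest.approx(0.0)

    def test_marginal(self, drug_params):
        occ = single_cell_occupancy(drug_params, 0.3, 2.0)
        assert single_cell_gf(0.0, 1.0, drug_params, 0.3, 2.0) == pytest.approx(
            1.0 - occ.P_E, abs=1e-12
        )


class TestPopulationGF:
    def test_normalization_random(self):
        rng = np.random.default_rng(5)
        for p in random_rate_grid(100, seed=11):
            pd = p.without_births()
            init = InitialComposition(
                N0=int(rng.integers(1, 30)),
                p0=("beta", rng.uniform(0.5, 4), rng.uniform(0.5, 4)),
            )
            t = rng.uniform(0.1, 5)
            assert population_gf(1.0, 1.0, pd, init, t) == pytest.approx(1.0, abs=1e-8)

    def test_single_cell_reduction(self, drug_params):
        init = InitialComposition(N0=1, p0=0.25)
        val = population_gf(0.3, 0.7, drug_params, init, 1.5)
        assert val == pytest.approx(
            single_cell_gf(0.3, 0.7, drug_params, 0.25, 1.5), abs=1e-12
        )

    def test_monte_carlo_oracle(self, drug_params):
        # g(z1, z2, t | p) is linear in p, so the Beta average of g^N0 has a
        # cheap vectorized Monte-Carlo oracle
        z1, z2, t, N0 = 0.4, 0.8, 1.0, 10
        g0 = single_cell_gf(z1, z2, drug_params, 0.0, t)
        g1 = single_cell_gf(z1, z2, drug_params, 1.0, t)
        rng = np.random.default_rng(77)
        p = rng.beta(2.0, 2.0, size=1_000_000)
        draws = (g0 + (g1 - g0) * p) ** N0
        mc, se = draws.mean(), draws.std(ddof=1) / np.sqrt(draws.size)
        init = InitialComposition(N0=N0, p0=("beta", 2.0, 2.0))
        val = population_gf(z1, z2, drug_params, init, t)
        assert abs(val - mc) < 3 * se

    def test_derivatives_give_mean(self, drug_params):
        init = InitialComposition(N0=20, p0=("beta", 2.0, 5.0))
        t = 1.2

        def g_of_z(z):
            return population_gf(z, z, drug_params, init, t)

        dG = richardson_derivative(g_of_z, 1.0)
        expected = mean_surviving_drug(drug_params, 20, init.p0_mean, t)
        assert dG == pytest.approx(expected, rel=1e-6)


class TestMeanSurvivingDrug:
    def test_t0(self, drug_params):
        assert mean_surviving_drug(drug_params, 200, 0.2, 0.0) == pytest.approx(200.0)

    def test_uniform_death(self):
        p = RateParameters(0, 0, 0.25, 0.25, 0.8, 0.3)
        for p0 in (0.0, 0.4, 1.0):
            assert mean_surviving_drug(p, 100, p0, 3.0) == pytest.approx(
                100 * np.exp(-0.75), rel=1e-12
            )

    def test_expm_oracle_example(self, drug_params):
        oracle = 200 * np.ones(2) @ (
            expm(drug_matrix(drug_params) * 2.0) @ np.array([0.8, 0.2])
        )
        assert mean_surviving_drug(drug_params, 200, 0.2, 2.0) == pytest.approx(
            oracle, abs=1e-10
        )

    def test_expm_oracle_random_grid(self):
        cases = random_rate_grid(50, seed=12)
        cases.append(RateParameters(0, 0, 0.3, 0.3, 0.2, 0.2))  # alpha0 = gamma0-2mu
        cases.append(RateParameters(0, 0, 0.3, 0.3 + 1e-11, 0.0, 0.0))  # alpha0 ~ 0
        for p in cases:
            pd = p.without_births()
            for t in (0.7, 4.0):
                oracle = 150 * np.ones(2) @ (
                    expm(drug_matrix(pd) * t) @ np.array([0.65, 0.35])
                )
                val = mean_surviving_drug(pd, 150, 0.35, t)
                assert val == pytest.approx(oracle, abs=1e-10 * max(1, oracle))

    def test_monotone_nonincreasing(self, drug_params):
        t = np.linspace(0, 20, 200)
        m = mean_surviving_drug(drug_params, 200, 0.3, t)
        assert np.all(np.diff(m) <= 1e-12)


class TestFanoDrug:
    def test_zero_heterogeneity_bound(self, drug_params):
        t = np.linspace(0.01, 20, 100)
        F = fano_drug(drug_params, 200, 0.2, 0.0, t)
        mean = mean_surviving_drug(drug_params, 200, 0.2, t)
        assert np.allclose(F, 1 - mean / 200, atol=1e-12)
        assert np.all(F < 1)

    def test_t0(self, drug_params):
        assert fano_drug(drug_params, 200, 0.2, 0.01, 0.0) == pytest.approx(0.0)

    def test_equal_death_rates_kill_heterogeneity_term(self):
        p = RateParameters(0, 0, 0.3, 0.3, 0.1, 0.1)
        F_het = fano_drug(p, 200, 0.4, 0.05, 2.0)
        F_none = fano_drug(p, 200, 0.4, 0.0, 2.0)
        assert F_het == pytest.approx(F_none, abs=1e-14)

    def test_binomial_enumeration_oracle(self, drug_params):
        # exact fixed-p0 oracle: enumerate Binomial(N0, p0) initial splits
        N0, p0, t = 5, 0.3, 1.5
        mean, var = binomial_mixture_moments(drug_params, N0, p0, t)
        assert fano_drug(drug_params, N0, p0, 0.0, t) == pytest.approx(
            var / mean, abs=1e-9
        )

    def test_beta_mixture_quadrature_oracle(self, drug_params):
        # distributed p0: integrate the binomial-split oracle over Beta(2, 5)
        from scipy.integrate import quad

        N0, t = 5, 1.5
        a, b = 2.0, 5.0

        def mixture(moment):
            def f(p):
                mean, var = binomial_mixture_moments(drug_params, N0, p, t)
                val = mean if moment == 1 else var + mean**2
                return val * beta_dist.pdf(p, a, b)

            return quad(f, 0, 1, epsabs=1e-11, epsrel=1e-11)[0]

        mean = mixture(1)
        var = mixture(2) - mean**2
        init = InitialComposition(N0=N0, p0=("beta", a, b))
        F = fano_drug(drug_params, N0, init.p0_mean, init.p0_var, t)
        assert F == pytest.approx(var / mean, abs=1e-7)

    def test_ssa_oracle(self, drug_params):
        from phenoswitch import ensemble_summary, simulate_ensemble

        init = InitialComposition(N0=200, p0=("beta", 2.0, 5.0))
        grid = np.array([0.0, 1.0])
        ens = simulate_ensemble(drug_params, init, grid, 10_000, seed=31)
        summ = ensemble_summary(ens, n_boot=500, boot_seed=1)
        F_pred = fano_drug(drug_params, 200, init.p0_mean, init.p0_var, 1.0)
        assert abs(summ.fano_N[1] - F_pred) < 3 * summ.fano_se[1]

    def test_undefined_at_extinction(self, drug_params):
        from phenoswitch import NumericalError

        with pytest.raises(NumericalError):
            fano_drug(drug_params, 200, 0.2, 0.0, 1e5)


class TestScriptF:
    def test_zero_variance(self, drug_params):
        assert script_F_theory(drug_params, 0.0, 2.0) == 0.0
        mean = mean_surviving_drug(drug_params, 200, 0.2, 2.0)
        F = 1 - mean / 200
        assert script_F_empirical(F, mean, 200) == pytest.approx(0.0, abs=1e-12)

    def test_t0(self, drug_params):
        assert script_F_theory(drug_params, 0.02, 0.0) == pytest.approx(0.0)

    def test_round_trip(self, drug_params):
        # theory and empirical agree when F and <N> come from the closed forms
        for t in (0.5, 1.0, 5.0):
            mean = mean_surviving_drug(drug_params, 200, 0.3, t)
            F = fano_drug(drug_params, 200, 0.3, 0.02, t)
            emp = script_F_empirical(F, mean, 200)
            th = script_F_theory(drug_params, 0.02, t)
            assert emp == pytest.approx(th, abs=1e-10)

    def test_negative_argument_warns(self):
        with pytest.warns(RuntimeWarning):
            out = script_F_empirical(0.0, 150.0, 200)
        assert np.isnan(out)


class TestMeanGrowth:
    def test_t0(self, growth_params):
        assert mean_growth(growth_params, 120, 80, 0.0) == pytest.approx(200.0)

    def test_pure_birth_death(self):
        p = RateParameters(0.4, 0.0, 0.1, 0.0, 0.0, 0.0)
        assert mean_growth(p, 50, 0, 3.0) == pytest.approx(
            50 * np.exp(0.3 * 3.0), rel=1e-12
        )

    def test_expm_oracle_example(self, growth_params):
        oracle = np.ones(2) @ (
            expm(growth_matrix(growth_params) * 10.0) @ np.array([200.0, 0.0])
        )
        assert mean_growth(growth_params, 200, 0, 10.0) == pytest.approx(
            oracle, abs=1e-10 * max(1, abs(oracle))
        )

    def test_expm_oracle_random_grid(self):
        for p in random_rate_grid(50, seed=13):
            for t in (0.5, 2.0):
                oracle = np.ones(2) @ (
                    expm(growth_matrix(p) * t) @ np.array([30.0, 20.0])
                )
                val = mean_growth(p, 30, 20, t)
                assert val == pytest.approx(oracle, rel=1e-10, abs=1e-10)


class TestMomentsGrowth:
    def test_t0(self, growth_params):
        ms = moments_growth(growth_params, 200, 50, [0.0])
        assert ms.EE[0] == pytest.approx(200**2, rel=1e-12)
        assert ms.MM[0] == pytest.approx(50**2, rel=1e-12)
        assert ms.EM[0] == pytest.approx(200 * 50, rel=1e-12)
        assert abs(ms.var_E[0]) < 1e-6 and abs(ms.var_N[0]) < 1e-6

    def test_classical_birth_death_variance(self):
        # Var(E) = E0 (k+mu)/(k-mu) e^{(k-mu)t} (e^{(k-mu)t} - 1)
        k, mu, E0, t = 0.4, 0.1, 50, 2.0
        p = RateParameters(k, 0.0, mu, 0.0, 0.0, 0.0)
        ms = moments_growth(p, E0, 0, [t])
        r = k - mu
        expected = E0 * (k + mu) / r * np.exp(r * t) * (np.exp(r * t) - 1)
        assert ms.var_E[0] == pytest.approx(expected, rel=1e-9)
        assert ms.var_M[0] == pytest.approx(0.0, abs=1e-9)

    def test_ode_oracle(self, growth_params):
        # independent route: stiff integration of the same closed linear system
        A = moment_matrix(growth_params)
        y0 = np.array([200.0, 0.0, 200.0**2, 0.0, 0.0])
        sol = solve_ivp(
            lambda t, y: A @ y, (0, 10), y0, t_eval=[1.0, 10.0],
            rtol=1e-12, atol=1e-9, method="LSODA",
        )
        ms = moments_growth(growth_params, 200, 0, [1.0, 10.0])
        assert np.allclose(ms.mean_E, sol.y[0], rtol=1e-8)
        assert np.allclose(ms.EE, sol.y[2], rtol=1e-8)
        assert np.allclose(ms.EM, sol.y[4], rtol=1e-6, atol=1e-6)

    def test_variance_decomposition_identity(self, growth_params):
        ms = moments_growth(growth_params, 100, 40, np.linspace(0, 10, 11))
        assert np.allclose(ms.var_N, ms.var_E + ms.var_M + 2 * ms.cov_EM, atol=0)

    def test_ssa_oracle(self, growth_params, growth_ensemble):
        from phenoswitch import ensemble_summary

        summ = ensemble_summary(growth_ensemble, n_boot=0)
        ms = moments_growth(growth_params, 200, 0, growth_ensemble.t_grid)
        n = growth_ensemble.n_replicates
        for j in range(1, growth_ensemble.t_grid.size):
            se_mean = np.sqrt(ms.var_N[j] / n)
            assert abs(summ.mean_N[j] - ms.mean_N[j]) < 3 * se_mean
            se_var = ms.var_N[j] * np.sqrt(2.0 / (n - 1))  # normal approx
            assert abs(summ.var_N[j] - ms.var_N[j]) < 4 * se_var

    def test_drug_phase_consistency(self, drug_params):
        # with births off, the 5-dim system reproduces the drug-phase mean
        t = np.array([0.5, 2.0, 5.0])
        ms = moments_growth(drug_params, 160, 40, t)
        assert np.allclose(
            ms.mean_N, mean_surviving_drug(drug_params, 200, 0.2, t), atol=1e-10
        )
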