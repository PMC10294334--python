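import numpy as np
import pytest
from scipy.special import betaln, comb, expit
from scipy.stats import binom, chi2

import dcakit as dk
from dcakit.errors import DomainError, ValidationError


def betabin_pmf_oracle(z, n, pbar, phi):
    """Closed-form pmf via the beta function, for single observations."""
    a = pbar * (1 / phi - 1)
    b = (1 - pbar) * (1 / phi - 1)
    return comb(n, z) * np.exp(betaln(z + a, n - z + b) - betaln(a, b))


class TestLoglik:
    def test_binomial_limit(self):
        z = np.array([2, 5, 17])
        n = np.array([10, 10, 40])
        p = np.array([0.3, 0.5, 0.4])
        ll_bb = dk.betabin_loglik(z, n, p, 1e-10)
        ll_b = binom.logpmf(z, n, p).sum()
        assert abs(ll_bb - ll_b) < 1e-4

    def test_symmetry_at_half(self):
        z = np.array([1, 4, 7])
        n = np.array([10, 10, 10])
        p = np.full(3, 0.5)
        assert dk.betabin_loglik(z, n, p, 0.1) == pytest.approx(
            dk.betabin_loglik(n - z, n, p, 0.1), abs=1e-10
        )

    def test_single_observation_closed_form(self):
        ll = dk.betabin_loglik([2], [5], [0.3], 0.2)
        assert ll == pytest.approx(np.log(betabin_pmf_oracle(2, 5, 0.3, 0.2)), abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            dk.betabin_loglik([1], [2], [0.5], 1.5)
        with pytest.raises(DomainError):
            dk.betabin_loglik([1], [2], [0.0], 0.1)
        with pytest.raises(DomainError):
            dk.betabin_loglik([3], [2], [0.5], 0.1)


class TestFit:
    def test_parameter_recovery(self, rng):
        S, n = 200, 2000
        w0, w1, phi = -1.0, 0.5, 0.05
        x1 = rng.integers(0, 2, S).astype(float)
        pbar = expit(w0 + w1 * x1)
        nu = 1 / phi - 1
        p = rng.beta(pbar * nu, (1 - pbar) * nu)
        z = rng.binomial(n, p)
        fit = dk.fit_betabin(z, np.full(S, n), np.column_stack([np.ones(S), x1]))
        assert fit.converged
        assert abs(fit.weights[1] - w1) < 0.1
        assert abs(fit.phi - phi) < 0.02

    def test_no_effect_gives_null_coefficient(self, rng):
        S, n = 40, 5000
        z = rng.binomial(n, 0.3, S)
        x1 = np.tile([0.0, 1.0], S // 2)
        fit = dk.fit_betabin(z, np.full(S, n), np.column_stack([np.ones(S), x1]))
        assert abs(fit.weights[1]) < 0.05

    def test_beats_grid_search_oracle(self):
        z = np.array([2, 5, 8, 15])
        n = np.array([20, 20, 20, 20])
        x1 = np.array([0.0, 0.0, 1.0, 1.0])
        design = np.column_stack([np.ones(4), x1])
        fit = dk.fit_betabin(z, n, design)
        best = -np.inf
        for w0 in np.linspace(-3, 1, 41):
            for w1 in np.linspace(-1, 3, 41):
                p = expit(w0 + w1 * x1)
                for phi in np.linspace(0.005, 0.6, 40):
                    best = max(best, dk.betabin_loglik(z, n, p, phi))
        assert fit.loglik >= best - 1e-3

    def test_free_phi_dominates_fixed_phi(self, rng):
        z = rng.binomial(500, 0.3, 10)
        n = np.full(10, 500)
        design = np.ones((10, 1))
        free = dk.fit_betabin(z, n, design)
        fixed = dk.fit_betabin(z, n, design, fixed_phi=0.2)
        assert free.loglik >= fixed.loglik - 1e-6
        assert fixed.fixed_phi and fixed.phi == 0.2

    def test_scale_consistency_of_weights(self, rng):
        z = rng.binomial(200, 0.4, 12)
        n = np.full(12, 200)
        x1 = np.tile([0.0, 1.0], 6)
        design = np.column_stack([np.ones(12), x1])
        fit1 = dk.fit_betabin(z, n, design, fixed_phi=0.05)
        fit10 = dk.fit_betabin(10 * z, 10 * n, design, fixed_phi=0.05)
        assert np.allclose(fit1.weights, fit10.weights, atol=0.02)

    def test_zero_total_observations_dropped(self, rng):
        z = np.array([3, 5, 0])
        n = np.array([10, 10, 0])
        fit = dk.fit_betabin(z, n, np.ones((3, 1)))
        assert fit.n_obs == 2

    def test_collinear_design_rejected(self):
        design = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValidationError):
            dk.fit_betabin([1, 2, 3, 4], [10] * 4, design)


class TestLrt:
    def test_equal_likelihoods(self):
        fit = dk.BetaBinFit(np.zeros(1), 0.1, -10.0, True, False, 5)
        res = dk.lrt(fit, fit, 1)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi_square_quantile(self):
        alt = dk.BetaBinFit(np.zeros(2), 0.1, -10.0, True, False, 5)
        null = dk.BetaBinFit(np.zeros(1), 0.1, -10.0 - 3.841 / 2, True, False, 5)
        res = dk.lrt(alt, null, 1)
        assert res.p_value == pytest.approx(chi2.sf(3.841, 1), abs=1e-12)
        assert res.p_value == pytest.approx(0.05, abs=5e-4)

    def test_statistic_clipped_nonnegative(self):
        alt = dk.BetaBinFit(np.zeros(2), 0.1, -10.0, True, False, 5)
        null = dk.BetaBinFit(np.zeros(1), 0.1, -9.9999999, True, False, 5)
        res = dk.lrt(alt, null, 1)
        assert res.statistic == 0.0 and 0 <= res.p_value <= 1


class TestGlobalPhi:
    def test_pooled_recovery(self, rng):
        # Dirichlet-multinomial counts with concentration A give every type
        # a beta-binomial marginal sharing phi = 1/(A + 1)
        S, n, phi = 40, 3000, 0.05
        base = np.array([0.2, 0.3, 0.5])
        alpha = base * (1 / phi - 1)
        counts = np.array(
            [rng.multinomial(n, rng.dirichlet(alpha)) for _ in range(S)]
        )
        table = dk.CellCountTable([f"s{i}" for i in range(S)], ["a", "b", "c"], counts)
        phi_hat = dk.estimate_global_phi(table)
        assert abs(phi_hat - phi) < 0.02

    def test_single_type_degenerates_to_intercept_fit(self, rng):
        counts = rng.binomial(100, 0.5, size=(6, 1))
        counts[:, 0] = np.maximum(counts[:, 0], 1)
        table = dk.CellCountTable([f"s{i}" for i in range(6)], ["only"], counts)
        phi_hat = dk.estimate_global_phi(table)
        assert 0 < phi_hat < 1
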