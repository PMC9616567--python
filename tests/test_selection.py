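"""Gamma-DFE expectations and fitting, alpha(x) and the asymptotic fit."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.special import comb

from envsel.selection import (
    alpha_lrt,
    alpha_of_x,
    dfe_bin_proportions,
    dfe_bootstrap_p,
    expected_sfs_gamma,
    fit_asymptotic_alpha,
    fit_dfe,
    mean_fixation_factor,
)
from envsel.sfs import SFSPair, fold_counts


def prf_bin_oracle(n, i, s):
    """Independent adaptive quadrature of the fixed-S sojourn integral."""
    def integrand(q):
        tau = (np.exp(-2 * s * q) - np.exp(-2 * s)) / (1 - np.exp(-2 * s))
        return tau / (q * (1 - q)) * comb(n, i) * q**i * (1 - q) ** (n - i)

    return quad(integrand, 0, 1, limit=200)[0]


def gamma_mix_oracle(n, i, shape, mean):
    """Nested adaptive quadrature over the gamma DFE (independent of the
    package's fixed log-grid scheme)."""
    g = stats.gamma(shape, scale=mean / shape)
    return quad(lambda s: prf_bin_oracle(n, i, s) * g.pdf(s), 0, np.inf,
                limit=400)[0]


class TestExpectedSfsGamma:
    def test_neutral_limit_matches_watterson(self):
        n, theta, L = 12, 0.004, 1e5
        e = expected_sfs_gamma(n, theta, 0.5, 1e-9, L=L)
        neutral = theta * L / np.arange(1, n)
        assert np.max(np.abs(e - neutral) / neutral) < 1e-6

    def test_strong_selection_suppresses_polymorphism(self):
        n, theta, L = 10, 0.005, 1e5
        e = expected_sfs_gamma(n, theta, 5.0, 5000.0, L=L)
        neutral_total = theta * L * np.sum(1.0 / np.arange(1, n))
        assert e.sum() < 0.01 * neutral_total

    def test_matches_nested_quadrature_oracle(self):
        n, shape, mean = 20, 0.3, 400.0
        e = expected_sfs_gamma(n, 1.0, shape, mean, L=1.0)
        for i in (1, 2, 10, 19):
            assert e[i - 1] == pytest.approx(
                gamma_mix_oracle(n, i, shape, mean), rel=2e-3
            )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            expected_sfs_gamma(3, 0.01, 0.3, 400.0)
        with pytest.raises(ValueError):
            expected_sfs_gamma(10, 0.01, -1.0, 400.0)
        with pytest.raises(ValueError):
            expected_sfs_gamma(10, 0.01, 0.3, 0.0)

    def test_distortion_multipliers_apply_per_bin(self):
        n = 8
        base = expected_sfs_gamma(n, 0.01, 0.3, 10.0)
        dist = np.linspace(0.5, 1.5, n - 1)
        assert np.allclose(expected_sfs_gamma(n, 0.01, 0.3, 10.0, distortion=dist),
                           base * dist)


def test_fixation_factor_limits():
    assert mean_fixation_factor(0.5, 1e-9) == pytest.approx(1.0, abs=1e-6)
    assert mean_fixation_factor(5.0, 5000.0) < 1e-3
    # single-point check against direct integration
    g = stats.gamma(0.3, scale=400.0 / 0.3)
    direct = quad(lambda s: 2 * s / np.expm1(min(2 * s, 700.0)) * g.pdf(s),
                  0, np.inf, limit=400)[0]
    assert mean_fixation_factor(0.3, 400.0) == pytest.approx(direct, rel=1e-3)


class TestFitDfe:
    def test_bins_from_independent_gamma_cdf(self):
        shape, mean = 0.7, 55.0
        g = stats.gamma(shape, scale=mean / shape)
        bins = dfe_bin_proportions(shape, mean)
        assert bins.sum() == pytest.approx(1.0, abs=1e-12)
        assert bins[0] == pytest.approx(g.cdf(1.0))
        assert bins[2] == pytest.approx(1 - g.cdf(10.0))

    def test_recovers_parameters_from_own_expectation(self):
        # noise-free spectrum at the expectation: optimizer-tolerance recovery
        n, theta, L = 20, 0.005, 2e5
        shape, mean = 0.3, 400.0
        xi_n = expected_sfs_gamma(n, theta * 2.76, shape, mean, L=L)
        xi_s = theta * L / np.arange(1, n)
        sfs = SFSPair(n=n, folded=False, xi_s=xi_s, xi_n=xi_n, l_s=L, l_n=L)
        fit = fit_dfe(sfs)
        assert fit.theta_s == pytest.approx(
            xi_s.sum() / (np.sum(1 / np.arange(1, n)) * L))
        assert np.abs(fit.bins - dfe_bin_proportions(shape, mean)).max() < 0.01

    def test_neutral_data_with_unit_multiplier_is_nearly_neutral(self):
        n, theta, L = 12, 0.01, 1e5
        xi = theta * L / np.arange(1, n)
        sfs = SFSPair(n=n, folded=False, xi_s=xi, xi_n=xi.copy(), l_s=L, l_n=L)
        fit = fit_dfe(sfs, theta_multiplier=1.0)
        assert fit.bins[0] > 0.95

    def test_folded_fitting_consistent_with_unfolded(self):
        n, theta, L = 20, 0.005, 5e5
        xi_n = expected_sfs_gamma(n, theta * 2.76, 0.3, 400.0, L=L)
        xi_s = theta * L / np.arange(1, n)
        folded = SFSPair(n=n, folded=True, xi_s=fold_counts(xi_s, n),
                         xi_n=fold_counts(xi_n, n), l_s=L, l_n=L)
        fit = fit_dfe(folded)
        assert np.abs(fit.bins - dfe_bin_proportions(0.3, 400.0)).max() < 0.02


class TestDfeBootstrapP:
    def _fit_with_bins(self, bins):
        from envsel.selection import DFEFit

        return DFEFit(shape=0.3, mean_2nes=400.0, theta_s=0.005, theta_n=0.0138,
                      bins=bins.mean(axis=0), loglik=0.0, n=20, folded=True,
                      bootstrap_bins=bins)

    def test_identical_replicates_give_p_one(self, rng):
        bins = rng.dirichlet(np.ones(3), size=200)
        p = dfe_bootstrap_p(self._fit_with_bins(bins), self._fit_with_bins(bins))
        assert (p == 1.0).all()

    def test_fully_separated_replicates_hit_floor(self, rng):
        a = np.column_stack([np.full(200, 0.8), np.full(200, 0.1), np.full(200, 0.1)])
        b = np.column_stack([np.full(200, 0.2), np.full(200, 0.4), np.full(200, 0.4)])
        p = dfe_bootstrap_p(self._fit_with_bins(a), self._fit_with_bins(b))
        assert np.allclose(p, 2 / 200)

    def test_matches_normal_approximation(self, rng):
        # paired differences engineered N(2*sd, sd): p ~ 2*Phi(-2)
        reps = 20000
        sd = 0.05
        diff = rng.normal(2 * sd, sd, size=reps)
        a = np.column_stack([0.5 + diff, 0.3 - diff / 2, 0.2 - diff / 2])
        b = np.column_stack([np.full(reps, 0.5), np.full(reps, 0.3), np.full(reps, 0.2)])
        p = dfe_bootstrap_p(self._fit_with_bins(a), self._fit_with_bins(b))
        expected = 2 * stats.norm.cdf(-2.0)
        assert p[0] == pytest.approx(expected, rel=0.25)

    def test_mismatched_replicates_rejected(self, rng):
        a = rng.dirichlet(np.ones(3), size=200)
        b = rng.dirichlet(np.ones(3), size=150)
        with pytest.raises(ValueError):
            dfe_bootstrap_p(self._fit_with_bins(a), self._fit_with_bins(b))


class TestAlphaOfX:
    def test_closed_form_examples(self):
        n = 3  # two polymorphic bins is too few; use direct construction
        sfs = SFSPair(n=10, folded=False,
                      xi_s=np.full(9, 20.0), xi_n=np.full(9, 10.0),
                      l_s=1000, l_n=1000, d_s=100.0, d_n=50.0)
        x, a = alpha_of_x(sfs)
        # pN/pS = 0.5 everywhere, dN/dS = 0.5 -> alpha = 0
        assert np.allclose(a, 0.0)

    @pytest.mark.parametrize("pn, expected", [(10, 0.0), (5, 0.5), (40, -3.0)])
    def test_single_bin_arithmetic(self, pn, expected):
        xi_n = np.array([float(pn)] + [1.0] * 8)
        xi_s = np.array([20.0] + [1.0] * 8)
        sfs = SFSPair(n=10, folded=False, xi_s=xi_s, xi_n=xi_n,
                      l_s=1000, l_n=1000, d_s=100.0, d_n=50.0)
        x, a = alpha_of_x(sfs)
        assert a[0] == pytest.approx(expected)

    def test_scale_invariance(self):
        sfs1 = SFSPair(n=10, folded=False, xi_s=np.arange(1, 10.0),
                       xi_n=np.arange(2, 11.0), l_s=1000, l_n=1000,
                       d_s=30.0, d_n=20.0)
        sfs2 = SFSPair(n=10, folded=False, xi_s=3 * np.arange(1, 10.0),
                       xi_n=3 * np.arange(2, 11.0), l_s=3000, l_n=3000,
                       d_s=90.0, d_n=60.0)
        _, a1 = alpha_of_x(sfs1)
        _, a2 = alpha_of_x(sfs2)
        assert np.allclose(a1, a2)

    def test_requires_unfolded_and_divergence(self):
        folded = SFSPair(n=10, folded=True, xi_s=np.ones(5), xi_n=np.ones(5),
                         l_s=100, l_n=100)
        with pytest.raises(ValueError):
            alpha_of_x(folded)
        nodiv = SFSPair(n=10, folded=False, xi_s=np.ones(9), xi_n=np.ones(9),
                        l_s=100, l_n=100, d_s=0.0, d_n=5.0)
        with pytest.raises(ValueError):
            alpha_of_x(nodiv)

    def test_zero_ps_bins_masked(self):
        xi_s = np.array([10.0, 0.0] + [5.0] * 7)
        sfs = SFSPair(n=10, folded=False, xi_s=xi_s, xi_n=np.ones(9),
                      l_s=100, l_n=100, d_s=10.0, d_n=5.0)
        x, a = alpha_of_x(sfs)
        assert len(x) == 8 and 0.2 not in x


class TestAsymptoticFit:
    def test_noise_free_recovery_to_1e6(self):
        a, b, c = 0.4, -0.3, 2.0
        x = np.arange(1, 20) / 20
        y = a + b * np.exp(-c * x)
        fit = fit_asymptotic_alpha(x, y)
        assert fit.a == pytest.approx(a, abs=1e-6)
        assert fit.b == pytest.approx(b, abs=1e-6)
        assert fit.c == pytest.approx(c, abs=1e-6)
        assert fit.alpha_asymptotic == pytest.approx(a + b * np.exp(-c), abs=1e-6)

    def test_constant_alpha_degenerate_exponent(self):
        x = np.arange(1, 20) / 20
        fit = fit_asymptotic_alpha(x, np.full_like(x, 0.2))
        assert fit.alpha_asymptotic == pytest.approx(0.2, abs=1e-6)
        assert abs(fit.b * np.exp(-fit.c)) < 1e-6

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_asymptotic_alpha(np.array([0.2, 0.4, 0.6]), np.zeros(3))

    def test_x_min_trims_low_frequency_bins(self):
        x = np.arange(1, 20) / 20
        y = 0.3 - 0.5 * np.exp(-3 * x)
        y_perturbed = y.copy()
        y_perturbed[0] = -5.0  # corrupt the singleton bin only
        fit = fit_asymptotic_alpha(x, y_perturbed, x_min=0.1)
        assert fit.alpha_asymptotic == pytest.approx(0.3 - 0.5 * np.exp(-3), abs=1e-6)


class TestAlphaLrt:
    def test_identical_datasets_null(self):
        x = np.arange(1, 20) / 20
        y = 0.4 - 0.3 * np.exp(-2 * x)
        stat, p = alpha_lrt(x, y, x, y.copy())
        assert stat == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_power_for_separated_asymptotes(self, rng):
        x = np.arange(1, 20) / 20
        y_set = 0.6 - 0.3 * np.exp(-2 * x) + rng.normal(0, 0.01, x.size)
        y_gen = 0.1 - 0.3 * np.exp(-2 * x) + rng.normal(0, 0.01, x.size)
        stat, p = alpha_lrt(x, y_set, x, y_gen)
        assert p < 0.01

    def test_type_one_error_calibrated(self, rng):
        x = np.arange(1, 20) / 20
        mu = 0.3 - 0.4 * np.exp(-2.5 * x)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            y1 = mu + rng.normal(0, 0.05, x.size)
            y2 = mu + rng.normal(0, 0.05, x.size)
            _, p = alpha_lrt(x, y1, x, y2)
            if p < 0.05:
                hits += 1
        # binomial 95% CI around 0.05 at 500 sims: [0.031, 0.069]
        assert 0.031 * n_sim <= hits <= 0.069 * n_sim
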