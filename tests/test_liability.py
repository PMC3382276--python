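"""Closed-form liability-threshold theory against independent oracles."""

import numpy as np
import pytest
from scipy import integrate, stats

import polyrisk as pr
from polyrisk.liability import LiabilityModel


class TestThresholdAndMoments:
    @pytest.mark.parametrize(
        "K, expected",
        [(0.5, 0.0), (0.1, 1.2816), (0.007, 2.457)],
    )
    def test_threshold_matches_normal_quantile(self, K, expected):
        assert pr.liability_threshold(K) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("K", [0.001, 0.01, 0.1, 0.3, 0.499])
    def test_case_control_means_balance(self, K):
        """K*i + (1-K)*i2 = 0: the population liability mean is zero."""
        m = LiabilityModel(K=K, h2=0.5)
        assert m.i > 0 > m.i2
        assert K * m.i + (1 - K) * m.i2 == pytest.approx(0.0, abs=1e-12)
        assert m.i == pytest.approx(m.z / K)

    @pytest.mark.parametrize("K", [-0.1, 0.0, 1.0, 1.5])
    def test_invalid_prevalence_rejected(self, K):
        with pytest.raises(ValueError):
            pr.liability_threshold(K)


class TestPenetrance:
    def test_half_at_threshold(self):
        for h2 in (0.1, 0.5, 0.9):
            m = LiabilityModel(K=0.1, h2=h2)
            assert pr.penetrance(m.T, m) == pytest.approx(0.5)

    @pytest.mark.parametrize("K, h2", [(0.1, 0.4), (0.007, 0.42), (0.3, 0.8)])
    def test_integrates_to_prevalence(self, K, h2):
        """E over the N(0, h2) genetic-load density recovers K."""
        m = LiabilityModel(K=K, h2=h2)
        val, _ = integrate.quad(
            lambda g: pr.penetrance(g, m) * stats.norm.pdf(g, scale=np.sqrt(h2)),
            -10, 10,
        )
        assert val == pytest.approx(K, rel=1e-6)

    def test_monotone_in_genetic_load(self):
        m = LiabilityModel(K=0.1, h2=0.4)
        g = np.linspace(-4, 4, 101)
        assert np.all(np.diff(pr.penetrance(g, m)) >= 0)

    def test_h2_one_is_step_function(self):
        m = LiabilityModel(K=0.1, h2=1.0)
        assert pr.penetrance(m.T - 1e-9, m) == 0.0
        assert pr.penetrance(m.T + 1e-9, m) == 1.0
        assert pr.penetrance(m.T, m) == 0.5


class TestMaxAuc:
    def test_uninformative_profile(self):
        assert pr.max_auc(LiabilityModel(K=0.1, h2=0.5), 0.0) == 0.5

    @pytest.mark.parametrize(
        "K, h2, expected",
        [(0.007, 0.42, 0.92), (0.007, 0.27, 0.87), (0.004, 0.35, 0.91)],
    )
    def test_cancer_configurations(self, K, h2, expected):
        """The three cancer parameterizations give ~0.92, 0.87, 0.91."""
        assert pr.max_auc(LiabilityModel(K=K, h2=h2)) == pytest.approx(
            expected, abs=0.006
        )

    @pytest.mark.parametrize("K", [0.004, 0.05, 0.2])
    @pytest.mark.parametrize("h2", [0.2, 0.42, 0.6])
    def test_matches_bivariate_liability_simulation(self, K, h2, rng):
        """Simulation oracle: profile = genetic part of a normal liability.

        The moments formula is a normal approximation to the truncated score
        distributions; on this disease-parameter grid its error is below
        2e-3 (see the integration cross-check below), well inside 3 MC SE.
        """
        n = 400_000
        g = rng.normal(0, np.sqrt(h2), n)
        liab = g + rng.normal(0, np.sqrt(1 - h2), n)
        case = liab > stats.norm.isf(K)
        n_ca = case.sum()
        ranks = stats.rankdata(g)
        empirical = (ranks[case].sum() - n_ca * (n_ca + 1) / 2) / (
            n_ca * (n - n_ca)
        )
        # Monte-Carlo SE of the AUC estimate (conservative Hanley-McNeil bound)
        se = np.sqrt(0.25 / min(n_ca, n - n_ca))
        assert pr.max_auc(LiabilityModel(K=K, h2=h2)) == pytest.approx(
            empirical, abs=3 * se + 1e-3
        )

    @pytest.mark.parametrize("K", [0.004, 0.02, 0.1])
    @pytest.mark.parametrize("h2", [0.2, 0.42, 0.6])
    def test_against_exact_integration_oracle(self, K, h2):
        """Numerical-integration oracle for the exact case/control score AUC.

        The truncated score densities are written down exactly and the
        concordance probability integrated numerically; the moments formula
        agrees to 3e-3 on this grid (the gap widens for h2 near 1 at common
        prevalences, a documented limit of the approximation).
        """
        from scipy import integrate

        T = stats.norm.isf(K)
        sd, resid = np.sqrt(h2), np.sqrt(1 - h2)
        grid = np.linspace(-8 * sd, 8 * sd, 4001)
        f_ctrl = stats.norm.pdf(grid, scale=sd) * stats.norm.cdf((T - grid) / resid) / (1 - K)
        f_case = stats.norm.pdf(grid, scale=sd) * stats.norm.sf((T - grid) / resid) / K
        F_ctrl = integrate.cumulative_trapezoid(f_ctrl, grid, initial=0)
        exact = integrate.trapezoid(f_case * F_ctrl, grid)
        assert pr.max_auc(LiabilityModel(K=K, h2=h2)) == pytest.approx(exact, abs=3e-3)

    def test_decreasing_in_prevalence(self):
        """Rarer disease, more extreme cases, better discrimination."""
        aucs = [
            pr.max_auc(LiabilityModel(K=K, h2=0.42)) for K in (0.004, 0.007, 0.04, 0.2)
        ]
        assert all(a > b for a, b in zip(aucs, aucs[1:]))

    def test_increasing_in_rho2(self):
        m = LiabilityModel(K=0.05, h2=0.6)
        aucs = [pr.max_auc(m, r) for r in (0.0, 0.1, 0.3, 0.6)]
        assert all(a < b for a, b in zip(aucs, aucs[1:]))

    def test_rho2_above_h2_rejected(self):
        with pytest.raises(ValueError):
            pr.max_auc(LiabilityModel(K=0.1, h2=0.3), 0.5)


class TestVarianceFromAuc:
    def test_auc_half_explains_nothing(self):
        assert pr.variance_from_auc(0.5, LiabilityModel(K=0.1, h2=0.5)) == 0.0

    @pytest.mark.parametrize("rho2", [0.1, 0.3])
    def test_round_trip(self, rho2):
        m = LiabilityModel(K=0.1, h2=0.5)
        share = pr.variance_from_auc(pr.max_auc(m, rho2), m)
        assert share * m.h2 == pytest.approx(rho2, abs=1e-6)

    def test_same_auc_wide_spread_across_diseases(self):
        """AUC 0.75 maps to very different genetic-variance shares."""
        shares = []
        for K in (0.001, 0.01, 0.1):
            for h2 in (0.3, 0.5, 0.8):
                m = LiabilityModel(K=K, h2=h2)
                if pr.max_auc(m) > 0.76:
                    shares.append(pr.variance_from_auc(0.75, m))
        assert min(shares) < 0.25
        assert max(shares) > 0.6

    def test_unattainable_auc_reports_maximum(self):
        m = LiabilityModel(K=0.1, h2=0.3)
        with pytest.raises(ValueError, match=r"0\.5"):
            pr.variance_from_auc(0.99, m)


class TestOrToLiabilityVariance:
    def test_null_odds_ratio(self):
        assert pr.or_to_liability_variance(0.3, 1.0, 0.1) == 0.0

    def test_monotone_in_odds_ratio(self):
        vals = [
            pr.or_to_liability_variance(0.2, orr, 0.05)
            for orr in (1.1, 1.5, 2.0, 4.0)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_rare_variant_envelope(self):
        """OR 3.74, MAF 1-5%, prevalence 1-20%: fractions of a percent to
        several percent of liability variance (order-of-magnitude envelope)."""
        vals = [
            pr.or_to_liability_variance(maf, 3.74, K)
            for maf in np.linspace(0.01, 0.05, 5)
            for K in np.linspace(0.01, 0.20, 10)
        ]
        assert min(vals) == pytest.approx(0.005, abs=0.002)
        assert max(vals) > 0.03
        assert max(vals) < 0.1

    def test_degenerate_maf_warns(self):
        with pytest.warns(UserWarning):
            assert pr.or_to_liability_variance(0.0, 2.0, 0.1) == 0.0

    def test_logit_method_same_order(self):
        probit = pr.or_to_liability_variance(0.2, 2.0, 0.05, "probit")
        logit = pr.or_to_liability_variance(0.2, 2.0, 0.05, "logit")
        assert 0.2 < logit / probit < 5.0


class TestPowerArithmetic:
    def test_null_variant_power_is_alpha(self):
        assert pr.gwas_power(1000, 0.0, 5e-8) == pytest.approx(5e-8)

    def test_eighty_percent_at_ncp(self):
        """NCP ~39.6 gives 80% power at genome-wide significance."""
        assert pr.gwas_power(39.6 / 0.005, 0.005, 5e-8) == pytest.approx(0.80, abs=2e-3)

    def test_power_increases_with_n(self):
        powers = [pr.gwas_power(n, 0.005, 5e-8) for n in (2000, 5000, 8000, 12000)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    @pytest.mark.parametrize("q2, expected, rel", [(0.005, 7900, 0.05), (0.08, 495, 0.02)])
    def test_required_sample_sizes(self, q2, expected, rel):
        assert pr.required_n(q2, 5e-8, 0.8) == pytest.approx(expected, rel=rel)

    @pytest.mark.parametrize("q2", [0.001, 0.01, 0.08])
    def test_inverse_consistency(self, q2):
        """required_n is the exact switch point of gwas_power."""
        n = pr.required_n(q2, 5e-8, 0.8)
        assert pr.gwas_power(n, q2, 5e-8) >= 0.8
        assert pr.gwas_power(n - 1, q2, 5e-8) < 0.8

    def test_ncp_additivity(self):
        """Doubling variance explained halves the required sample size."""
        n1 = pr.required_n(0.004, 5e-8, 0.8)
        n2 = pr.required_n(0.008, 5e-8, 0.8)
        assert n2 == pytest.approx(n1 / 2, abs=1)
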