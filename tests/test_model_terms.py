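"""Each model term against closed-form Normal / Poisson oracles
(scipy.stats, independent of the package's own density code)."""

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import norm, poisson

from deerssm import (
    block_count_loglik,
    carcass_loglik,
    growth_randomwalk_logdensity,
    harvest_loglik,
    hunting_submodel_logdensity,
    process_mean_regular,
    process_mean_winter,
    road_count_loglik,
    seasonal_rate_recursion_logdensity,
    winter_mortality_submodel_logdensity,
)


class TestProcessMeans:
    def test_identity_with_no_growth_no_hunting(self):
        assert process_mean_regular(5.0, 0.0, -np.inf) == pytest.approx(5.0)
        assert process_mean_winter(5.0, 0.0, -np.inf, -np.inf) == pytest.approx(5.0)

    def test_regular_transition_arithmetic(self):
        # h = 0.5 removes log 2 from the log abundance
        assert process_mean_regular(5.0, 0.1, 0.0) == pytest.approx(
            5.0 + 0.1 + np.log(0.5)
        )
        assert process_mean_regular(0.0, -0.2, -np.inf) == pytest.approx(-0.2)

    def test_winter_applies_growth_twice_plus_mortality(self):
        assert process_mean_winter(6.0, 0.05, -np.inf, 0.0) == pytest.approx(
            6.0 + 0.1 + np.log(0.5)
        )
        # winter minus regular at identical inputs isolates rl + log(1-d)
        reg = process_mean_regular(6.0, 0.05, -1.0)
        win = process_mean_winter(6.0, 0.05, -1.0, -2.0)
        assert win - reg == pytest.approx(0.05 + np.log1p(-expit(-2.0)))

    def test_certain_mortality_rejected(self):
        with pytest.raises(ValueError):
            process_mean_winter(6.0, 0.0, 0.0, np.inf)
        with pytest.raises(ValueError):
            process_mean_regular(6.0, 0.0, np.inf)


class TestSubmodelDensities:
    def test_hunting_zero_residual(self):
        Ef = np.array([3.0, 10.0, 0.0])
        hl = -5.0 + 0.08 * Ef
        out = hunting_submodel_logdensity(hl, -5.0, 0.08, Ef, 1.0)
        assert out == pytest.approx(3 * norm.logpdf(0.0, 0.0, 1.0))

    def test_hunting_single_term_matches_normal_pdf(self):
        out = hunting_submodel_logdensity(
            np.array([0.0]), 0.0, 0.08, np.array([10.0]), 1.0
        )
        assert out == pytest.approx(norm.logpdf(0.0, 0.8, 1.0))

    def test_hunting_zero_effort_collapses_to_baseline(self):
        hl = np.array([-4.0, -5.0])
        out = hunting_submodel_logdensity(hl, -4.5, 0.3, np.zeros(2), 0.7)
        assert out == pytest.approx(norm.logpdf(hl, -4.5, 0.7).sum())

    def test_winter_mortality_matches_normal_pdf(self):
        # at the study's reference coefficients, a 76-day SD50 winter has
        # mean mortality logit -0.41 -> mean rate ~0.399
        eps = -4.97 + 0.06 * 76.0
        assert eps == pytest.approx(-0.41)
        assert expit(eps) == pytest.approx(0.3989, abs=1e-4)
        out = winter_mortality_submodel_logdensity(
            np.array([-0.2]), -4.97, 0.06, np.array([76.0]), 3.03
        )
        assert out == pytest.approx(norm.logpdf(-0.2, eps, 3.03))

    def test_snowless_winters_collapse_to_intercept(self):
        dl = np.array([-5.2, -4.4])
        out = winter_mortality_submodel_logdensity(
            dl, -4.97, 0.06, np.zeros(2), 3.03
        )
        assert out == pytest.approx(norm.logpdf(dl, -4.97, 3.03).sum())

    def test_growth_random_walk(self):
        assert growth_randomwalk_logdensity(
            np.array([0.0, 0.1]), 0.06
        ) == pytest.approx(norm.logpdf(0.1, 0.0, 0.06))
        const = growth_randomwalk_logdensity(np.full(5, 0.3), 0.2)
        assert const == pytest.approx(4 * norm.logpdf(0.0, 0.0, 0.2))
        assert growth_randomwalk_logdensity(np.array([0.5]), 0.1) == 0.0

    def test_seasonal_recursion(self):
        # every 4-window summing to zero -> pure normalisation constants
        rsl = np.array([0.2, -0.1, 0.3, -0.4, 0.2, -0.1, 0.3, -0.4])
        out = seasonal_rate_recursion_logdensity(rsl, 0.5)
        assert out == pytest.approx(5 * norm.logpdf(0.0, 0.0, 0.5))
        out = seasonal_rate_recursion_logdensity(
            np.array([0.0, 0.0, 0.0, 0.5]), 0.77
        )
        assert out == pytest.approx(norm.logpdf(0.5, 0.0, 0.77))

    @pytest.mark.parametrize(
        "fn, args",
        [
            (growth_randomwalk_logdensity, (np.zeros(3),)),
            (seasonal_rate_recursion_logdensity, (np.zeros(5),)),
            (
                hunting_submodel_logdensity,
                (np.zeros(3), 0.0, 0.0, np.zeros(3)),
            ),
            (
                winter_mortality_submodel_logdensity,
                (np.zeros(3), 0.0, 0.0, np.zeros(3)),
            ),
        ],
    )
    def test_nonpositive_scale_rejected(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args, 0.0)


class TestChannelLikelihoods:
    def test_road_single_cell_matches_poisson_pmf(self):
        # N=1000, R=0.10, rS=0.5, O=10, A=0.00153 -> mean 0.765
        out = road_count_loglik(
            C=np.array([[1]]),
            NL=np.array([np.log(1000.0)]),
            R=np.array([0.10]),
            rsl=np.array([0.0]),
            O=np.array([[10]]),
            A=np.array([0.00153]),
        )
        assert out == pytest.approx(poisson.logpmf(1, 0.765))
        assert out == pytest.approx(np.log(0.765) - 0.765)

    def test_road_zero_occasions_skipped(self):
        out = road_count_loglik(
            C=np.array([[7]]), NL=np.array([5.0]), R=np.array([0.5]),
            rsl=np.array([0.0]), O=np.array([[0]]), A=np.array([0.001]),
        )
        assert out == 0.0

    def test_road_zero_count(self):
        out = road_count_loglik(
            C=np.array([[0]]), NL=np.array([np.log(1000.0)]),
            R=np.array([0.10]), rsl=np.array([0.0]),
            O=np.array([[10]]), A=np.array([0.00153]),
        )
        assert out == pytest.approx(-0.765)

    def test_block_mean_and_zero_rate(self):
        theta = 1000.0 * 0.21 * 0.0393
        assert theta == pytest.approx(8.253)
        out = block_count_loglik(
            np.array([5]), np.array([np.log(1000.0)]), 0.21, np.array([0.0393])
        )
        assert out == pytest.approx(poisson.logpmf(5, theta))
        assert block_count_loglik(
            np.array([3]), np.array([np.log(1000.0)]), 0.0, np.array([0.0393])
        ) == -np.inf

    def test_harvest_matches_poisson_pmf(self):
        NL = np.array([np.log(500.0)])
        hl = np.array([logit(0.02)])
        assert harvest_loglik(np.array([10]), NL, hl) == pytest.approx(
            poisson.logpmf(10, 10.0)
        )
        assert poisson.logpmf(10, 10.0) == pytest.approx(-2.0785, abs=1e-4)
        assert harvest_loglik(np.array([0]), NL, hl) == pytest.approx(-10.0)
        # vanishing rate with zero count contributes nothing
        assert harvest_loglik(
            np.array([0]), NL, np.array([-1e8])
        ) == pytest.approx(0.0, abs=1e-8)

    def test_carcass_mean_and_boundaries(self):
        NL = np.array([np.log(2000.0)])
        dl = np.array([logit(0.05)])
        eta = 2000.0 * 0.05 * 0.77 * 0.1
        assert eta == pytest.approx(7.7)
        assert carcass_loglik(
            np.array([4]), NL, dl, 0.77, np.array([0.1])
        ) == pytest.approx(poisson.logpmf(4, eta))
        assert carcass_loglik(
            np.array([0]), NL, dl, 0.77, np.array([0.1])
        ) == pytest.approx(-7.7)
        assert carcass_loglik(
            np.array([2]), NL, np.array([-1e9]), 0.77, np.array([0.1])
        ) == -np.inf
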