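"""Joint density: term-by-term oracle equivalence, additivity, gradients.

The oracle below re-implements the whole joint density with scipy.stats
loops, sharing no code with the package's density functions.
"""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import cauchy, norm, poisson

from deerssm import ModelConfig, full_log_posterior
from deerssm._posterior import UnconstrainedPosterior

from conftest import make_toy


def oracle_log_posterior(params, data, config):
    """Straightforward summation of every stated density (scipy.stats)."""
    time = data.time
    T = time.T
    winters = list(time.winter_transitions)
    s1, s2, s3, s4, s5, s6 = params.sigma
    Sn = data.snow_days if config.snow_covariate == "sd50" else data.snow_max

    lp = norm.logpdf(params.NL[0], 0, config.nl1_prior_sd)
    lp += norm.logpdf(params.rl[0], 0, config.rl1_prior_sd)
    s0 = config.rsl_init_sd if config.rsl_init_sd is not None else s6
    for i in range(3):
        lp += norm.logpdf(params.rsl[i], 0, s0)
    for coef in (params.hm, params.rho, params.b, params.a):
        lp += norm.logpdf(coef, 0, config.coef_prior_sd)
    for s in params.sigma:
        lp += np.log(2) + cauchy.logpdf(s, 0, config.sigma_prior_scale)

    h = expit(params.hl)
    d = expit(params.dl)
    for t in range(2, T + 1):  # 1-based period
        i = t - 1
        mu = params.NL[i - 1] + params.rl[i] + np.log(1 - h[i - 1])
        if t in winters:
            w = winters.index(t)
            mu += params.rl[i] + np.log(1 - d[w])
            lp += norm.logpdf(params.NL[i], mu, s2)
        else:
            lp += norm.logpdf(params.NL[i], mu, s1)
        lp += norm.logpdf(params.rl[i], params.rl[i - 1], s3)
        lp += norm.logpdf(
            params.hl[i - 1], params.hm + params.rho * data.effort[i], s4
        )
    for w, t in enumerate(winters):
        lp += norm.logpdf(params.dl[w], params.b + params.a * Sn[w], s5)
    for i in range(3, T):
        lp += norm.logpdf(
            params.rsl[i] + params.rsl[i - 1] + params.rsl[i - 2]
            + params.rsl[i - 3],
            0, s6,
        )

    N = np.exp(params.NL)
    rS = expit(params.rsl)
    if config.use_road:
        for i in range(T):
            for m in range(len(data.routes)):
                if data.road_occasions[i, m] > 0:
                    mean = (
                        N[i] * params.R[m] * rS[i]
                        * data.road_occasions[i, m] * data.route_area_ratio[m]
                    )
                    lp += poisson.logpmf(data.road_counts[i, m], mean)
    if config.use_harvest:
        for i in range(1, T):
            lp += poisson.logpmf(data.harvest[i], N[i] * h[i - 1])
    if config.use_block:
        for w, t in enumerate(winters):
            lp += poisson.logpmf(
                data.block_counts[w],
                N[t - 1] * params.bc * data.block_area_ratio[w],
            )
    if config.use_carcass:
        for w, t in enumerate(winters):
            lp += poisson.logpmf(
                data.carcasses[w],
                N[t - 1] * d[w] * params.rD * data.carcass_area_ratio[w],
            )
    return float(lp)


@pytest.mark.parametrize("T,routes", [(8, ("A", "B")), (8, ("A", "B", "E")),
                                      (48, ("A", "B", "E"))])
def test_full_log_posterior_matches_oracle(T, routes):
    rng = np.random.default_rng(123)
    for _ in range(8):
        data, params = make_toy(rng, T=T, routes=routes)
        for config in (ModelConfig(), ModelConfig(snow_covariate="maxs")):
            got = full_log_posterior(params, data, config)
            want = oracle_log_posterior(params, data, config)
            assert got == pytest.approx(want, rel=1e-10)


def test_channel_toggles_are_additive():
    rng = np.random.default_rng(7)
    data, params = make_toy(rng, T=8)
    base_kw = dict(use_road=False, use_block=False, use_harvest=False,
                   use_carcass=False)
    lp_none = full_log_posterior(params, data, ModelConfig(**base_kw))
    total = full_log_posterior(params, data, ModelConfig())
    acc = lp_none
    for channel in ("road", "block", "harvest", "carcass"):
        kw = dict(base_kw)
        kw[f"use_{channel}"] = True
        acc += full_log_posterior(params, data, ModelConfig(**kw)) - lp_none
    assert total == pytest.approx(acc, rel=1e-12)


def test_snow_covariate_switch_changes_only_mortality_term():
    rng = np.random.default_rng(8)
    data, params = make_toy(rng, T=8)
    diff = full_log_posterior(params, data, ModelConfig(snow_covariate="maxs")) \
        - full_log_posterior(params, data, ModelConfig())
    want = (
        norm.logpdf(params.dl, params.b + params.a * data.snow_max,
                    params.sigma[4]).sum()
        - norm.logpdf(params.dl, params.b + params.a * data.snow_days,
                      params.sigma[4]).sum()
    )
    assert diff == pytest.approx(want, rel=1e-10)


def test_out_of_support_is_minus_infinity():
    rng = np.random.default_rng(9)
    data, params = make_toy(rng, T=8)
    params.sigma[2] = -0.1
    assert full_log_posterior(params, data) == -np.inf
    data2, params2 = make_toy(rng, T=8)
    params2.bc = 1.5
    assert full_log_posterior(params2, data2) == -np.inf


def test_zero_mean_against_positive_count_is_minus_infinity():
    rng = np.random.default_rng(10)
    data, params = make_toy(rng, T=8)
    data.block_counts[:] = 5
    params.bc = 0.0
    assert full_log_posterior(params, data) == -np.inf


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(42)
    data, params = make_toy(rng, T=8, routes=("A", "B", "E"))
    return data, params


class TestUnconstrainedPosterior:
    def test_value_equals_centred_density_plus_jacobian(self, toy):
        data, params = toy
        post = UnconstrainedPosterior(data, engine="numpy")
        q = post.unconstrain(params)
        got = post.logp(q)
        want = full_log_posterior(params, data) + post.log_jacobian(q)
        assert got == pytest.approx(want, rel=1e-12)

    def test_reconstruct_inverts_unconstrain(self, toy):
        data, params = toy
        post = UnconstrainedPosterior(data, engine="numpy")
        q = post.unconstrain(params)
        back = post.reconstruct(q)
        for name in ("NL", "rl", "hl", "dl", "rsl", "sigma", "R"):
            np.testing.assert_allclose(
                getattr(back, name), getattr(params, name), rtol=1e-12
            )
        assert back.bc == pytest.approx(params.bc)

    def test_gradient_matches_finite_differences(self, toy):
        data, params = toy
        post = UnconstrainedPosterior(data, engine="numpy")
        rng = np.random.default_rng(3)
        q = post.unconstrain(params) + 0.05 * rng.standard_normal(post.dim)
        lp, g = post.logp_grad(q)
        assert np.isfinite(lp)
        eps = 1e-6
        for i in range(post.dim):
            qp, qm = q.copy(), q.copy()
            qp[i] += eps
            qm[i] -= eps
            fd = (post.logp(qp) - post.logp(qm)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=5e-5, abs=1e-5)

    def test_compiled_kernel_agrees_with_reference(self, toy):
        data, params = toy
        ref = UnconstrainedPosterior(data, engine="numpy")
        fast = UnconstrainedPosterior(data, engine="numba")
        rng = np.random.default_rng(4)
        q0 = ref.unconstrain(params)
        for _ in range(20):
            q = q0 + 0.5 * rng.standard_normal(ref.dim)
            lp_ref, g_ref = ref.logp_grad(q)
            lp_fast, g_fast = fast.logp_grad(q)
            if not np.isfinite(lp_ref):
                assert lp_fast == lp_ref
                continue
            assert lp_fast == pytest.approx(lp_ref, rel=1e-10)
            np.testing.assert_allclose(g_fast, g_ref, rtol=1e-8, atol=1e-8)
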