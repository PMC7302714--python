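"""Joint Bayesian state-space model of bimonthly deer population dynamics.

Latent process
--------------
The log expected abundance ``NL_t = log N_t`` evolves on the bimonthly grid.
Between two observed periods (a regular two-month step)::

    NL_t ~ Normal(NL_{t-1} + rl_t + log(1 - h_t), sigma1^2)

and across the snowbound Jan-Apr gap (the winter transition, a four-month
step, so growth acts twice on the log scale and winter mortality applies)::

    NL_t ~ Normal(NL_{t-1} + 2 rl_t + log(1 - h_t) + log(1 - d_t), sigma2^2)

``rl_t`` (log growth rate) follows a Gaussian random walk with scale
``sigma3``.  The hunting rate on the logit scale is hierarchically tied to
hunting effort, ``hl_t ~ Normal(hm + rho * Ef_t, sigma4^2)``, and the winter
mortality rate to a snow covariate, ``dl_t ~ Normal(b + a * Sn_t, sigma5^2)``
(``Sn`` is SD50 — days with snow deeper than 50 cm — or the maximum snow
depth MaxS in the variant model).

Observation channels (all conditionally Poisson given the latents)
------------------------------------------------------------------
road counts    C_{t,m} ~ Poisson(N_t * R_m * rS_t * O_{t,m} * A_c[m])
block counts   B_t     ~ Poisson(N_t * bc * A_b[t])          (winter t only)
harvest        H_t     ~ Poisson(N_t * h_t)                  (t >= 2)
carcasses      D_t     ~ Poisson(N_t * d_t * rD * A_d[t])    (winter t only)

``rS_t = inv_logit(rsl_t)`` is a seasonal observability effect whose four
consecutive values sum to noise, ``rsl_t = -(rsl_{t-1}+rsl_{t-2}+rsl_{t-3})
+ omega_t``, giving an annual, approximately sum-to-zero cycle.

Priors: Normal(0, 100^2) on NL_1, hm, rho, b, a; half-Cauchy(0, 10) on the
six scale parameters; Uniform(0, 1) on R_m, bc, rD.  Initialisation of
``rl_1`` (Normal(0, 1)) and ``rsl_{1..3}`` (Normal(0, sigma6)) is
configurable since the hierarchical statements leave them free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, xlogy

from .data import SurveyData

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))
_TINY_MEAN = 1e-12


def _normal_logpdf(x, mu, sigma) -> np.ndarray:
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI


def _half_cauchy_logpdf(x, scale) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.log(2.0 / np.pi) - np.log(scale) - np.log1p((x / scale) ** 2)
    return np.where(x > 0, out, -np.inf)


def _poisson_logpmf(k, mu) -> np.ndarray:
    """Poisson log pmf with the model's numeric guards.

    A mean below 1e-12 is treated as exactly zero: it contributes ~0 for a
    zero count and -inf for a positive one.
    """
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    small = mu < _TINY_MEAN
    safe_mu = np.where(small, 0.0, mu)
    out = xlogy(k, safe_mu) - safe_mu - gammaln(k + 1.0)
    return np.where(small & (k > 0), -np.inf, out)


def _log1m_expit(x) -> np.ndarray:
    """log(1 - inv_logit(x)) = -softplus(x), stable for large |x|."""
    return -np.logaddexp(0.0, np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# configuration and parameter container


@dataclass
class ModelConfig:
    """Model variant switches, prior constants and channel toggles."""

    snow_covariate: str = "sd50"  # 'sd50' or 'maxs'
    use_road: bool = True
    use_block: bool = True
    use_harvest: bool = True
    use_carcass: bool = True
    nl1_prior_sd: float = 100.0
    rl1_prior_sd: float = 1.0
    #: prior SD of rsl_1..rsl_3; None ties it to sigma6
    rsl_init_sd: float | None = None
    coef_prior_sd: float = 100.0
    sigma_prior_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.snow_covariate not in ("sd50", "maxs"):
            raise ValueError("snow_covariate must be 'sd50' or 'maxs'")

    def snow_series(self, data: SurveyData) -> np.ndarray:
        return data.snow_days if self.snow_covariate == "sd50" else data.snow_max


@dataclass
class ModelParams:
    """One point in parameter space (latent states + hyperparameters).

    ``NL``, ``rl`` and ``rsl`` have length T; ``hl`` has length T-1 (periods
    t = 2..T); ``dl`` one entry per winter transition; ``sigma`` holds
    (sigma1..sigma6); ``R`` one observation rate per route.
    """

    NL: np.ndarray
    rl: np.ndarray
    hl: np.ndarray
    dl: np.ndarray
    rsl: np.ndarray
    hm: float
    rho: float
    b: float
    a: float
    sigma: np.ndarray
    R: np.ndarray
    bc: float
    rD: float

    def __post_init__(self) -> None:
        for name in ("NL", "rl", "hl", "dl", "rsl", "sigma", "R"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def N(self) -> np.ndarray:
        return np.exp(self.NL)

    def in_support(self) -> bool:
        return bool(
            np.all(self.sigma > 0)
            and np.all((self.R >= 0) & (self.R <= 1))
            and 0 <= self.bc <= 1
            and 0 <= self.rD <= 1
            and all(
                np.all(np.isfinite(getattr(self, n)))
                for n in ("NL", "rl", "hl", "dl", "rsl")
            )
            and np.isfinite([self.hm, self.rho, self.b, self.a]).all()
        )


# ---------------------------------------------------------------------------
# process means


def process_mean_regular(NL_prev: float, rl_t: float, hl_t: float) -> float:
    """Mean of NL_t for a regular two-month transition."""
    mu = NL_prev + rl_t + float(_log1m_expit(hl_t))
    if mu == -np.inf:
        raise ValueError("hunting rate of 1 gives a degenerate process mean")
    return mu


def process_mean_winter(
    NL_prev: float, rl_t: float, hl_t: float, dl_t: float
) -> float:
    """Mean of NL_t for a winter transition: growth twice, plus mortality."""
    mu = (
        NL_prev
        + 2.0 * rl_t
        + float(_log1m_expit(hl_t))
        + float(_log1m_expit(dl_t))
    )
    if mu == -np.inf:
        raise ValueError(
            "hunting or winter mortality rate of 1 gives a degenerate process mean"
        )
    return mu


# ---------------------------------------------------------------------------
# submodel log-densities


def growth_randomwalk_logdensity(rl: np.ndarray, sigma3: float) -> float:
    """Random walk on the log growth rate: rl_t ~ Normal(rl_{t-1}, sigma3^2)."""
    if sigma3 <= 0:
        raise ValueError("sigma3 must be positive")
    rl = np.asarray(rl, dtype=float)
    if rl.size < 2:
        return 0.0
    return float(np.sum(_normal_logpdf(rl[1:], rl[:-1], sigma3)))


def hunting_submodel_logdensity(
    hl: np.ndarray, hm: float, rho: float, Ef: np.ndarray, sigma4: float
) -> float:
    """hl_t ~ Normal(hm + rho * Ef_t, sigma4^2) over t = 2..T."""
    if sigma4 <= 0:
        raise ValueError("sigma4 must be positive")
    hl = np.asarray(hl, dtype=float)
    Ef = np.asarray(Ef, dtype=float)
    if hl.shape != Ef.shape:
        raise ValueError("hl and effort series must be aligned")
    return float(np.sum(_normal_logpdf(hl, hm + rho * Ef, sigma4)))


def winter_mortality_submodel_logdensity(
    dl: np.ndarray, b: float, a: float, Sn: np.ndarray, sigma5: float
) -> float:
    """dl_t ~ Normal(b + a * Sn_t, sigma5^2) at winter transitions."""
    if sigma5 <= 0:
        raise ValueError("sigma5 must be positive")
    dl = np.asarray(dl, dtype=float)
    Sn = np.asarray(Sn, dtype=float)
    if dl.shape != Sn.shape:
        raise ValueError("dl and snow series must be aligned")
    return float(np.sum(_normal_logpdf(dl, b + a * Sn, sigma5)))


def seasonal_rate_recursion_logdensity(rsl: np.ndarray, sigma6: float) -> float:
    """Sum-to-noise recursion: rsl_t + rsl_{t-1} + rsl_{t-2} + rsl_{t-3} ~
    Normal(0, sigma6^2) for t >= 4.  The first three values are handled by
    the initialisation prior, not here."""
    if sigma6 <= 0:
        raise ValueError("sigma6 must be positive")
    rsl = np.asarray(rsl, dtype=float)
    if rsl.size < 4:
        return 0.0
    window = rsl[3:] + rsl[2:-1] + rsl[1:-2] + rsl[:-3]
    return float(np.sum(_normal_logpdf(window, 0.0, sigma6)))


# ---------------------------------------------------------------------------
# observation-channel log-likelihoods


def road_count_loglik(
    C: np.ndarray,
    NL: np.ndarray,
    R: np.ndarray,
    rsl: np.ndarray,
    O: np.ndarray,
    A: np.ndarray,
) -> float:
    """Poisson likelihood of the road counts; cells with no survey are skipped."""
    C = np.asarray(C, dtype=float)
    O = np.asarray(O, dtype=float)
    N = np.exp(np.asarray(NL, dtype=float))
    rS = expit(np.asarray(rsl, dtype=float))
    mu = N[:, None] * np.asarray(R)[None, :] * rS[:, None] * O * np.asarray(A)[None, :]
    mask = O > 0
    ll = float(np.sum(_poisson_logpmf(C[mask], mu[mask])))
    if ll == -np.inf:
        logger.warning("road channel: zero Poisson mean faces a positive count")
    return ll


def block_count_loglik(
    B: np.ndarray, NL_winter: np.ndarray, bc: float, A_b: np.ndarray
) -> float:
    """Poisson likelihood of the block counts at winter transitions."""
    theta = np.exp(np.asarray(NL_winter, dtype=float)) * bc * np.asarray(A_b)
    ll = float(np.sum(_poisson_logpmf(B, theta)))
    if ll == -np.inf:
        logger.warning("block channel: zero Poisson mean faces a positive count")
    return ll


def harvest_loglik(H: np.ndarray, NL: np.ndarray, hl: np.ndarray) -> float:
    """Poisson likelihood of the nuisance-control harvest, t = 2..T."""
    lam = np.exp(np.asarray(NL, dtype=float)) * expit(np.asarray(hl, dtype=float))
    return float(np.sum(_poisson_logpmf(H, lam)))


def carcass_loglik(
    D: np.ndarray,
    NL_winter: np.ndarray,
    dl: np.ndarray,
    rD: float,
    A_d: np.ndarray,
) -> float:
    """Poisson likelihood of the thaw carcass counts at winter transitions."""
    eta = (
        np.exp(np.asarray(NL_winter, dtype=float))
        * expit(np.asarray(dl, dtype=float))
        * rD
        * np.asarray(A_d)
    )
    ll = float(np.sum(_poisson_logpmf(D, eta)))
    if ll == -np.inf:
        logger.warning("carcass channel: zero Poisson mean faces a positive count")
    return ll


# ---------------------------------------------------------------------------
# full joint density


def full_log_posterior(
    params: ModelParams, data: SurveyData, config: ModelConfig | None = None
) -> float:
    """Unnormalised log posterior density of ``params`` given ``data``.

    Sum of the process terms, the four hierarchical submodels, the enabled
    observation channels and all priors.  Returns ``-inf`` outside the
    support.
    """
    config = config or ModelConfig()
    if not params.in_support():
        return -np.inf
    time = data.time
    T = time.T
    widx = data.winter_index  # 0-based indices of winter-transition periods
    s1, s2, s3, s4, s5, s6 = params.sigma
    Sn = config.snow_series(data)

    lp = 0.0
    # priors
    lp += float(_normal_logpdf(params.NL[0], 0.0, config.nl1_prior_sd))
    lp += float(_normal_logpdf(params.rl[0], 0.0, config.rl1_prior_sd))
    rsl_sd = config.rsl_init_sd if config.rsl_init_sd is not None else s6
    lp += float(np.sum(_normal_logpdf(params.rsl[:3], 0.0, rsl_sd)))
    for coef in (params.hm, params.rho, params.b, params.a):
        lp += float(_normal_logpdf(coef, 0.0, config.coef_prior_sd))
    lp += float(np.sum(_half_cauchy_logpdf(params.sigma, config.sigma_prior_scale)))
    # Uniform(0,1) priors on R, bc, rD contribute 0 inside the support

    # process: regular transitions with sigma1, winter transitions with sigma2
    h = expit(params.hl)  # aligned to periods t = 2..T
    winter_mask = np.zeros(T, dtype=bool)
    winter_mask[widx] = True
    w_of = {i: w for w, i in enumerate(widx)}
    for i in range(1, T):
        if winter_mask[i]:
            mu = process_mean_winter(
                params.NL[i - 1], params.rl[i], params.hl[i - 1],
                params.dl[w_of[i]],
            )
            lp += float(_normal_logpdf(params.NL[i], mu, s2))
        else:
            mu = process_mean_regular(
                params.NL[i - 1], params.rl[i], params.hl[i - 1]
            )
            lp += float(_normal_logpdf(params.NL[i], mu, s1))

    lp += growth_randomwalk_logdensity(params.rl, s3)
    lp += hunting_submodel_logdensity(
        params.hl, params.hm, params.rho, data.effort[1:], s4
    )
    lp += winter_mortality_submodel_logdensity(params.dl, params.b, params.a, Sn, s5)
    lp += seasonal_rate_recursion_logdensity(params.rsl, s6)

    if config.use_road:
        lp += road_count_loglik(
            data.road_counts, params.NL, params.R, params.rsl,
            data.road_occasions, data.route_area_ratio,
        )
    if config.use_block:
        lp += block_count_loglik(
            data.block_counts, params.NL[widx], params.bc, data.block_area_ratio
        )
    if config.use_harvest:
        lp += harvest_loglik(data.harvest[1:], params.NL[1:], params.hl)
    if config.use_carcass:
        lp += carcass_loglik(
            data.carcasses, params.NL[widx], params.dl, params.rD,
            data.carcass_area_ratio,
        )
    return lp if np.isfinite(lp) else -np.inf
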