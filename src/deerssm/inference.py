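"""Posterior sampling, convergence diagnostics and posterior summaries.

``run_mcmc`` samples the joint posterior with NUTS on the unconstrained
(mixed centred / non-centred) parameterisation, then maps retained draws
back to the constrained parameters.  The default protocol mirrors the original study
analysis: 4 chains, 30,000 warmup iterations, 60,000 post-warmup iterations
per chain thinned to 1% (600 retained per chain, 2,400 total).  Reduced
settings for simulation experiments are available via
``MCMCSettings.reduced()``.  Convergence is judged by the split-chain
potential scale reduction factor, with R-hat < 1.1 taken as converged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nuts import NutsDiagnostics, nuts_sample
from ._posterior import UnconstrainedPosterior
from .data import SurveyData
from .model import ModelConfig

RHAT_THRESHOLD = 1.1

SCALAR_PARAMS = (
    "hm", "rho", "b", "a",
    "sigma1", "sigma2", "sigma3", "sigma4", "sigma5", "sigma6",
    "R_A", "R_B", "R_E", "bc", "rD",
)
VECTOR_PARAMS = ("NL", "rl", "hl", "dl", "rsl")


@dataclass
class MCMCSettings:
    """Sampler protocol.  Defaults reproduce the study protocol.

    ``iterations`` is the number of post-warmup iterations *per chain*;
    ``thin`` retains every ``thin``-th draw (thinning to 1% = every 100th).
    """

    chains: int = 4
    warmup: int = 30_000
    iterations: int = 60_000
    thin: int = 100
    target_accept: float = 0.8
    max_treedepth: int = 10
    init: str = "map"  # 'map' (mode + jitter) or 'random'
    jitter: float = 0.05
    #: re-run a chain (fresh sub-seed, higher target acceptance) when more
    #: than `retry_divergence_frac` of its retained transitions diverged —
    #: the signature of step-size adaptation collapsing into a funnel neck
    max_chain_retries: int = 2
    retry_divergence_frac: float = 0.1
    #: two-stage cross-chain adaptation: short adaptive pilot chains pool
    #: their draws into one diagonal metric (inflated along any direction
    #: where pilots disagree, i.e. the slowly mixing ones), then the final
    #: chains run with that metric fixed and only the step size tuned
    cross_adapt: bool = False
    pool_draws: int = 300
    final_warmup: int = 300

    def __post_init__(self) -> None:
        if min(self.chains, self.warmup, self.iterations, self.thin) < 1:
            raise ValueError("chains, warmup, iterations and thin must be positive")

    @classmethod
    def reduced(cls, chains: int = 4, warmup: int = 2000,
                iterations: int = 2000, thin: int = 2,
                target_accept: float = 0.9, **kw) -> "MCMCSettings":
        """Reduced-scale protocol for simulation experiments: 1,000 retained
        draws per chain (2,000 iterations thinned by 2)."""
        return cls(chains=chains, warmup=warmup, iterations=iterations,
                   thin=thin, target_accept=target_accept, **kw)

    @property
    def retained_per_chain(self) -> int:
        return self.iterations // self.thin

    @property
    def total_retained(self) -> int:
        return self.chains * self.retained_per_chain


@dataclass
class PosteriorDraws:
    """Retained MCMC draws keyed by parameter name.

    Scalar parameters have shape ``(chains, draws)``; latent state vectors
    ``(chains, draws, len)``.  ``meta`` records the protocol, seed and
    per-chain sampler diagnostics.
    """

    draws: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws["hm"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["hm"].shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for ``name`` with the chain axis flattened away."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_arviz(self):
        import arviz as az

        return az.from_dict(posterior=self.draws)


def _split_rhat_1d(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor of one scalar quantity.

    Each chain is halved, then the classic between/within variance ratio is
    computed over the 2x chains.  Identical constant chains return 1.0 by
    convention.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[1] // 2
    if n < 2:
        raise ValueError("need at least 4 draws per chain for split R-hat")
    halves = np.concatenate([x[:, :n], x[:, x.shape[1] - n:]], axis=0)
    if np.ptp(halves) == 0.0:
        return 1.0
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = n * chain_means.var(ddof=1)
    if W == 0.0:
        return np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def split_rhat(draws: "PosteriorDraws | np.ndarray", parameter: str | None = None):
    """Split R-hat for one parameter (scalar -> float, vector -> array)."""
    if isinstance(draws, PosteriorDraws):
        if draws.n_chains < 2:
            raise ValueError("split R-hat requires at least 2 chains")
        arr = draws.draws[parameter]
    else:
        arr = np.asarray(draws, dtype=float)
        if arr.ndim != 2 and arr.ndim != 3:
            raise ValueError("expected (chains, draws[, k]) array")
        if arr.shape[0] < 2:
            raise ValueError("split R-hat requires at least 2 chains")
    if arr.ndim == 2:
        return _split_rhat_1d(arr)
    return np.array([_split_rhat_1d(arr[:, :, k]) for k in range(arr.shape[2])])


def run_mcmc(
    data: SurveyData,
    config: ModelConfig | None = None,
    settings: MCMCSettings | None = None,
    seed: int | None = None,
) -> PosteriorDraws:
    """Sample the model posterior given ``data``.

    Chains are run sequentially from a jittered posterior mode (or random
    points), each with an independent stream spawned from ``seed``; the same
    seed, settings and data always reproduce identical draws.
    """
    config = config or ModelConfig()
    settings = settings or MCMCSettings()
    post = UnconstrainedPosterior(data, config)
    ss = np.random.SeedSequence(seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    chain_seeds = ss.spawn(settings.chains)

    if settings.chains < 2:
        warnings.warn("fewer than 2 chains: split R-hat will be unavailable")

    inv_metric = None
    if settings.init == "map":
        center = post.map_point(init_rng)
        # curvature at the mode seeds the mass matrix; the warmup windows
        # refine it from actual draws
        inv_metric = post.hessian_inv_metric(center)
    elif settings.init == "random":
        center = None
    else:
        raise ValueError(f"unknown init strategy {settings.init!r}")

    def start_point(rng):
        if center is None:
            return post.initial_point(rng)
        for _ in range(100):
            q0 = center + settings.jitter * rng.standard_normal(post.dim)
            if np.isfinite(post.logp(q0)):
                return q0
        return center

    if settings.cross_adapt:
        # stage A: short adaptive pilots; the coordinate-wise median of
        # their draw variances becomes the fixed final metric (median, not
        # pooled variance: one pilot trapped in a minor mode must not blow
        # up the scale of a whole direction)
        pooled = []
        for cs in ss.spawn(settings.chains):
            rng = np.random.default_rng(cs)
            pilot_draws, _ = nuts_sample(
                post.logp_grad, start_point(rng), settings.warmup,
                settings.pool_draws, rng,
                target_accept=settings.target_accept,
                max_treedepth=settings.max_treedepth,
                inv_metric=inv_metric,
            )
            pooled.append(pilot_draws.var(axis=0))
        inv_metric = np.clip(np.median(np.stack(pooled), axis=0), 1e-8, None)
        final_warmup = settings.final_warmup
        adapt_metric = False
    else:
        final_warmup = settings.warmup
        adapt_metric = True

    n_keep = settings.retained_per_chain
    per_chain_q = np.empty((settings.chains, n_keep, post.dim))
    diags: list[NutsDiagnostics] = []
    retries = []
    for c, cs in enumerate(chain_seeds):
        attempt_seeds = cs.spawn(settings.max_chain_retries + 1)
        for attempt, aseed in enumerate(attempt_seeds):
            rng = np.random.default_rng(aseed)
            q0 = start_point(rng)
            chain_draws, diag = nuts_sample(
                post.logp_grad, q0, final_warmup, settings.iterations, rng,
                target_accept=min(0.99, settings.target_accept + 0.05 * attempt),
                max_treedepth=settings.max_treedepth,
                inv_metric=inv_metric,
                adapt_metric=adapt_metric,
            )
            frac = diag.divergences / settings.iterations
            if frac <= settings.retry_divergence_frac or attempt == len(attempt_seeds) - 1:
                break
            warnings.warn(
                f"chain {c}: {diag.divergences} divergent transitions "
                f"({frac:.0%}); re-running with a fresh sub-seed"
            )
        retries.append(attempt)
        per_chain_q[c] = chain_draws[settings.thin - 1 :: settings.thin][:n_keep]
        diags.append(diag)
        if diag.divergences:
            warnings.warn(
                f"chain {c}: {diag.divergences} divergent transitions after warmup"
            )

    # map retained draws back to the constrained parameters
    scalar_names = [
        n for n in SCALAR_PARAMS
        if not n.startswith("R_") or n[2:] in data.routes
    ]
    out: dict[str, np.ndarray] = {
        name: np.empty((settings.chains, n_keep)) for name in scalar_names
    }
    T, W = data.time.T, data.time.n_winters
    shapes = {"NL": T, "rl": T, "hl": T - 1, "dl": W, "rsl": T}
    for name, k in shapes.items():
        out[name] = np.empty((settings.chains, n_keep, k))
    for c in range(settings.chains):
        for i in range(n_keep):
            p = post.reconstruct(per_chain_q[c, i])
            out["hm"][c, i] = p.hm
            out["rho"][c, i] = p.rho
            out["b"][c, i] = p.b
            out["a"][c, i] = p.a
            for j in range(6):
                out[f"sigma{j + 1}"][c, i] = p.sigma[j]
            for m, route in enumerate(data.routes):
                out[f"R_{route}"][c, i] = p.R[m]
            out["bc"][c, i] = p.bc
            out["rD"][c, i] = p.rD
            for name in VECTOR_PARAMS:
                out[name][c, i] = getattr(p, name)

    meta = {
        "settings": settings,
        "seed": seed,
        "snow_covariate": config.snow_covariate,
        "chain_retries": retries,
        "divergences": [d.divergences for d in diags],
        "warmup_divergences": [d.warmup_divergences for d in diags],
        "step_sizes": [d.step_size for d in diags],
        "mean_accept": [d.mean_accept for d in diags],
        "mean_treedepth": [d.mean_treedepth for d in diags],
    }
    return PosteriorDraws(draws=out, meta=meta)


def summarize_posterior(
    draws: PosteriorDraws, forest_area_km2: float | None = None
) -> pd.DataFrame:
    """Posterior mean, central 95% interval and split R-hat per parameter.

    Latent vectors are expanded to one row per component (1-based period
    index).  When ``forest_area_km2`` is given, derived rows for the
    expected abundance ``N[t] = exp(NL_t)`` and the density per km^2 are
    appended (without R-hat: they are deterministic transforms of NL).
    """
    can_rhat = draws.n_chains >= 2 and draws.n_draws >= 4
    if not can_rhat:
        warnings.warn("R-hat unavailable: need >= 2 chains and >= 4 draws")
    rows = []

    def _row(name, values, rhat):
        rows.append({
            "parameter": name,
            "mean": float(np.mean(values)),
            "q2.5": float(np.quantile(values, 0.025)),
            "q97.5": float(np.quantile(values, 0.975)),
            "rhat": rhat,
        })

    for name in SCALAR_PARAMS:
        if name not in draws.draws:
            continue
        arr = draws.draws[name]
        _row(name, arr, _split_rhat_1d(arr) if can_rhat else np.nan)
    for name in VECTOR_PARAMS:
        if name not in draws.draws:
            continue
        arr = draws.draws[name]
        rh = split_rhat(arr) if can_rhat else np.full(arr.shape[2], np.nan)
        for k in range(arr.shape[2]):
            t = k + 2 if name in ("hl",) else k + 1
            _row(f"{name}[{t}]", arr[:, :, k], float(rh[k]))
    if forest_area_km2 is not None and "NL" in draws.draws:
        N = np.exp(draws.draws["NL"])
        for k in range(N.shape[2]):
            _row(f"N[{k + 1}]", N[:, :, k], np.nan)
            _row(f"density[{k + 1}]", N[:, :, k] / forest_area_km2, np.nan)
    df = pd.DataFrame(rows).set_index("parameter")
    df["converged"] = df["rhat"] < RHAT_THRESHOLD
    return df
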