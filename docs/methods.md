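# Methods

## The model

`deerssm` estimates the bimonthly dynamics of a closed sika deer
(*Cervus nippon*) population in a 46.12 km² cool-temperate forest from four
noisy count channels collected over twelve years (2007–2018).  The year is
divided into four two-month survey periods (May–Jun … Nov–Dec); the
snowbound January–April gap is unobserved, so the step from a Nov–Dec
period to the next May–Jun period (the *winter transition*, periods
t = 5, 9, …, 45 on the 48-period grid) spans four months.

**Process model.**  With `NL_t = log N_t` the log expected abundance,
`rl_t` the log growth rate, `h_t` the hunting (nuisance-control) rate and
`d_t` the winter mortality rate,

    NL_t ~ Normal(NL_{t-1} +   rl_t + log(1-h_t),              sigma1²)   regular step
    NL_t ~ Normal(NL_{t-1} + 2·rl_t + log(1-h_t) + log(1-d_t), sigma2²)   winter transition

Growth acts twice across the four-month winter gap, hence the doubled
`rl_t`.  The growth rate follows a Gaussian random walk,
`rl_t ~ Normal(rl_{t-1}, sigma3²)` — deliberately without density
dependence, which is out of scope for this small, homogeneous site.
Hunting and mortality logits are hierarchically regressed on covariates:

    hl_t ~ Normal(hm + rho·Ef_t, sigma4²)        Ef_t = hunter-days in period t
    dl_t ~ Normal(b  + a·Sn_t,  sigma5²)         Sn_t = SD50 (days of snow > 50 cm)
                                                  or MaxS (cm) in the variant model

**Observation model.**  All channels are conditionally Poisson given the
latent states (marginally a Poisson/log-normal mixture; no extra
overdispersion term is added):

    road counts    C_{t,m} ~ Poisson(N_t · R_m · rS_t · O_{t,m} · A_c[m])
    block counts   B_t     ~ Poisson(N_t · bc · A_b[t])      winter transitions only
    harvest        H_t     ~ Poisson(N_t · h_t)              t ≥ 2
    carcasses      D_t     ~ Poisson(N_t · d_t · rD · A_d[t]) winter transitions only

`R_m`, `bc`, `rD` are per-channel observation/detection rates;
`A_c`, `A_b`, `A_d` are the surveyed fractions of the forest; `O_{t,m}`
counts route-m survey occasions in period t (cells with `O = 0` carry no
likelihood).  The seasonal observability logit `rsl_t` (leaf phenology,
deer activity) follows a sum-to-noise annual cycle,
`rsl_t = -(rsl_{t-1}+rsl_{t-2}+rsl_{t-3}) + omega_t`,
`omega_t ~ Normal(0, sigma6²)`, so any four consecutive values sum to
noise.

**Priors.**  `Normal(0, 100²)` on `NL_1`, `hm`, `rho`, `b`, `a`;
half-Cauchy(0, 10) on `sigma1..sigma6`; `Uniform(0, 1)` on `R_m`, `bc`,
`rD`.  Two initialisations are not pinned down by the hierarchical
statements and are configurable:

* `rl_1 ~ Normal(0, 1)` — weakly informative on a bimonthly log growth
  rate (`ModelConfig.rl1_prior_sd`);
* `rsl_1..rsl_3 ~ Normal(0, sigma6)` — matching the noise scale of the
  recursion (`ModelConfig.rsl_init_sd`; a fixed value may be substituted).

## Data conventions

* Harvest at t = 1 (May–Jun 2007) has no model term; the likelihood starts
  at t = 2.  Hunting rates are defined for every t ≥ 2 even when effort is
  zero; zero harvests then pull `h_t` down.
* The missing December 2017 block count is imputed as the mean of 2016 and
  2018, rounded half-up (configurable) because the channel is Poisson.
* Route strip ratios come from route length × 15 m width / forest area
  (0.153%, 0.107%, 0.023% for A/B/E).  The published ratio list labels the
  third route "c"; it is mapped to route E.
* The carcass-search strip width is not measured; the default 50 m is a
  configuration constant, and only the product `rD · A_d` is identified —
  rescaling the width rescales the fitted `rD` inversely.
* Raw per-drive road records (15-minute independence filter, record
  completeness) are assumed cleaned upstream; the loader consumes bimonthly
  aggregates, which are what the likelihood uses.

## Posterior computation

No probabilistic-programming backend is used: the joint log density and its
exact gradient are authored directly (`deerssm._posterior`), with a numba
translation (`deerssm._kernels`) that evaluates in ~10 µs; the NumPy
version is the reference and the two are asserted to agree in the tests.
Sampling uses a multinomial No-U-Turn sampler with dual-averaging step-size
adaptation and windowed diagonal mass-matrix estimation
(`deerssm._nuts`), the sampler family used for the original analysis.

Parameterisation was chosen by the data regime:

* `NL`, `hl`, `dl`, `rsl` are sampled *centred* (the states themselves are
  coordinates): the count data are strongly informative about them, which
  is the regime where centring is well conditioned;
* the growth walk `rl` is *non-centred* (standardised innovations): its
  innovation scale `sigma3` is small and weakly identified, and centring
  it produces a funnel;
* scales enter as `log sigma`, rates as logits, with the Jacobians included.

Chains start from a jittered posterior mode (L-BFGS with the analytic
gradient, best of three starts) and the mass matrix is seeded with the
inverse diagonal curvature at the mode; both choices shorten warmup
substantially because coordinate scales span several orders of magnitude.
Divergent transitions (energy error > 1000) are counted and reported,
never dropped silently.

Two sampler-robustness devices are built in.  A chain whose retained
transitions diverge at more than 10% is re-run with a fresh sub-seed and a
higher acceptance target (at most twice, recorded in the metadata): that
divergence rate is the signature of step-size adaptation having collapsed
into the neck of a scale-parameter funnel, which traps the chain.  An
optional two-stage scheme (`MCMCSettings.cross_adapt`) runs short adaptive
pilot chains and fixes the final chains' metric at the coordinate-wise
median of the pilots' draw variances.

The default protocol mirrors the original analysis: 4 chains, 30,000
warmup iterations, 60,000 post-warmup iterations per chain thinned to 1%
(600 retained per chain, 2,400 total).  `MCMCSettings.reduced()` (4 chains,
2,000 warmup, 2,000 post-warmup iterations thinned by 2 — 1,000 retained
per chain — target acceptance 0.9) is the scale used by the test suite, the
examples and the acceptance script; it runs in one to two minutes per fit.  Convergence is judged by split-chain
R-hat < 1.1, computed directly from the BDA3 split-chain formula (constant
chains return 1 by convention) and cross-checked against ArviZ.

## Synthetic data

`scenario_from_study_defaults()` packages the study conditions: the
12-year grid, the programme's hunting-effort table and winter snow/carcass
covariates, the strip geometry above, and the reference structural
estimates (hm = −6.06, rho = 0.08, b = −4.97, a = 0.06, sigma = 0.29,
0.69, 0.06, 0.99, 3.03, 0.77, R = 0.10/0.13/0.75, bc = 0.21, rD = 0.77) as
simulation truth.  Latent trajectories are drawn from the hierarchical
distributions (a `noise_free` flag pins them at their means for closed-form
oracle checks), then counts from the Poisson models.

Two generator choices are package decisions:

* **Survey design.**  Per-period road occasions are not published; the
  default design is a constant 90/60/30 occasions per period for routes
  A/B/E, matching the programme's overall volume (~8,600 usable drives).
* **Plausibility screening.**  `rl` integrates into `NL` twice, so
  unconditional trajectories occasionally reach absurd abundances (10⁻¹⁰
  or 10¹¹ animals).  Latent trajectories are redrawn until `N_t` stays
  within `population_bounds` (default 50–50,000 animals, i.e. roughly
  1–1,000 per km²) — simulation from the model *conditioned on an
  ecologically possible trajectory*.  The screening slightly biases the
  realised distribution of the growth path (and hence recovery of
  `sigma3`-adjacent quantities) but leaves the structural parameters'
  meaning untouched; it can be disabled.

The generator emulates the study's structure, not its every nuance: no
observer behaviour, no spatial structure, no age/sex classes, and the
per-period occasion design is stylised.  Passing recovery tests therefore
demonstrate that the estimation machinery is self-consistent under the
model, not that the model is correct for the real forest.

## Problem sizes used by tests and the acceptance run

Simulation–refit experiments use the full 48-period, three-route study
grid with the reduced MCMC protocol above.  The recovery experiment
repeats 10 simulate–fit rounds; coverage of each structural parameter's
95% interval and split R-hat of the structural parameters are assessed at
that scale.  Posterior predictive checks use 1,000 replicates, the
protocol's check size.

## Numerical choices

* `log(1-h)` is computed as `-softplus(hl)`; rates via stable `expit`.
* A Poisson mean below 1e-12 is treated as zero: it contributes −∞ against
  a positive count (flagged) and ~0 against a zero count.
* `NL > 690` (abundance beyond double-precision `exp`) is rejected as
  out of support rather than overflowing.
* Quantile intervals are equal-tailed empirical quantiles; posterior means
  are plain averages over retained draws.
* The density-overlay check uses a Gaussian KDE with the normal-reference
  bandwidth and reports the fraction of grid points where the observed
  density lies inside the pointwise replicate min–max band; channels with
  a single distinct value are plotted as a spike and yield `nan` coverage
  with a warning.

## Known limitations

* The latent seasonal-observability states (`rsl`, `sigma6`) and `sigma1`
  mix an order of magnitude more slowly than the structural parameters;
  at the reduced protocol their split R-hat can exceed 1.1 on some
  datasets even when every structural parameter has converged.  The full
  study protocol (90,000 iterations/chain) is the appropriate scale for
  inference on those states.
* Winters with zero carcasses leave the corresponding mortality logits
  identified only from above, so the snow-effect intercept `b` has a long
  lower tail; its posterior is honest but wide.
* Detectability is not separately estimable from these data (no repeated
  structure): all abundance statements are expected counts through the
  channel rates, not detection-corrected population sizes.
* The block channel assigns each December count to the following winter
  transition, inheriting the study's convention; no interpolation across
  the winter gap is attempted.
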