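# Methods

## The model

`otaria` fits a Bayesian state-space surplus-production model to a
harvested, then recovering, pinniped population observed through sparse
shore-count surveys.

**Process model.** Absolute abundance follows a discrete-time budget

    N_t = N_{t-1} + f(N_{t-1}) - H_{t-1} - M_{t-1},

where `H_t` is the commercial harvest, `M_t` the fisheries bycatch, and the
surplus-production function is the generalized theta-logistic
(Pella–Tomlinson) form

    f(N) = R_max N (1 - (N/K)^z).

`R_max` is the maximum per-capita growth rate (1/yr), `K` the carrying
capacity (thousands of animals) and `z` a shape parameter: `z = 1` gives the
ordinary (Schaefer) logistic with peak production at `K/2`; `z > 1` moves the
production peak to `K (1+z)^{-1/z}`, i.e. density dependence that only bites
near `K`.  Two structural variants are fitted: *linear* (`z` fixed at 1) and
*non-linear* (`z` estimated, uniform prior on (1e-4, 10)).

The model is reparameterized in relative abundance `P_t = N_t / K`, which
decorrelates the latent states from `K`.  The population is assumed at
carrying capacity before removals begin (`N_t = K` for all years up to 1928),
expressed as a single shared deviation for the whole pre-harvest block:

    P_{1900..1928} = e^{U_1}
    P_t = (P_{t-1} + R_max P_{t-1}(1 - P_{t-1}^z) - H_{t-1}/K - M_{t-1}/K) e^{U_t}

with i.i.d. process deviations `U_t ~ Normal(0, sigma2)`.  A config switch
(`shared_pre_block=False` in the generator) provides the alternative reading
with independent yearly pre-block deviations; the shared draw is the default
because the block is defined by a single subscripted deviation.

**Observation model.** Survey indices are proportional, lognormally noisy
measurements

    I_t = q K P_t e^{V_t},   V_t ~ Normal(0, tau2),

with detectability `q` in (0,1) (the fraction of the population ashore and
counted).  Missing survey years simply contribute nothing to the likelihood.

**Units.** `K`, `N_t`, `I_t` are in thousands of animals throughout; removal
series are entered in animals and divided by 1000 internally.  The prior
median of `K` (`e^{5.7} ≈ 299` thousand) pins this convention.

## Priors

| parameter | default prior | rationale |
|---|---|---|
| `R_max` | lognormal(-2.9, 0.5) | median `e^{-2.9} ≈ 0.055`/yr, CV 50%, spanning published pinniped growth-rate estimates (0.037–0.084) |
| `K` | lognormal(5.7, 0.8) | median ≈ 299 thousand, CV ≈ 100% (0.947 exactly) |
| `z` | uniform(1e-4, 10) | non-informative over plausible shapes |
| `q` | beta(2.2, 2) | mean 0.524, wide; detection studies give 0.38–0.74 |
| `sigma2` | inverse-gamma(1, 0.4) | shape–scale convention, density ∝ x^{-(a+1)} e^{-b/x}; diffuse, roughly flat in log x |
| `tau2` | inverse-gamma(3, 0.8) | as above, mildly tighter |

The inverse-gamma arguments are read as shape–scale (mode `b/(a+1)`, so
invgamma(1, 0.4) has mode 0.2).  Nine alternative specifications (`sen1`–
`sen9`) alter exactly one prior each for the sensitivity analysis: a wider
uniform for `z`; uniform, log-shifted (±30% on the log scale) and
higher-CV variants for `K`; doubled/halved canonical parameters for the two
variance priors.

## Posterior computation

The free variables are the six parameters (on transformed scales: log for
`R_max`, `K`, `sigma2`, `tau2`; logit for `q`; raw for `z`) and the free
deviation vector `U` (one shared pre-block draw plus one per year after
1928).  `P_t` is a deterministic function of `(params, U, removals)`, which
mirrors the state equation and keeps parameter–state correlations low.

If a proposed `(params, U)` drives any pre-noise bracket non-positive the
joint density is `-inf` and the proposal is rejected; the posterior is the
prior × likelihood restricted to feasible paths, with no truncation or
flooring of states during inference.  One consequence worth knowing: with
*no* data the posterior is the feasibility-truncated prior, which visibly
tilts the `R_max`, `z` and `sigma2` marginals (the `K`, `q`, `tau2`
marginals are untouched because, absent removals, they do not enter the
bracket).  The no-data test therefore checks the unconstrained marginals
against their priors exactly and the constrained ones against a
rejection-sampled truncated-prior oracle.

The sampler is an adaptive Metropolis-within-Gibbs scan (numba-compiled):

- one Gaussian random-walk update per parameter coordinate per iteration;
- one *joint* update of all free parameter coordinates drawn from an
  adaptively estimated covariance (Haario-style running moments, refreshed
  every 50 iterations).  Single-site updates alone mix very slowly along the
  strongly correlated `K`–`q` and `R_max`–`z` ridges; the joint move is what
  brings split-chain agreement (R-hat) near 1 at practical run lengths;
- one update per free deviation `U_t`, with tail-only recomputation of the
  state path (updating `U_t` only changes `P_s` for `s ≥ t`);
- per-coordinate proposal scales adapt in batches of 50 toward acceptance
  0.44 (0.234 for the joint move) with a diminishing step
  `min(0.1, 1/sqrt(batch))`.  Adaptation *continues past burn-in*: the hard
  feasibility boundary can wedge a chain whose frozen scales are too large
  (observed as zero acceptances over thousands of iterations); a
  diminishing-adaptation scheme remains ergodic and lets the scales shrink
  out of the wedge.

Chain design defaults mirror the study: 3 independent chains × 1,000,000
iterations, burn-in 100,000, thinning 50 (`MCMCConfig.full()`).  Tests and
simulation studies use `MCMCConfig.scaled()` (3 × 20,000 / 2,000 / 10); the
reported single-fit summaries in `scripts/acceptance.py` use one-tenth of
the full design (3 × 100,000 / 10,000 / 50), which reaches R-hat ≈ 1.0 on
typical synthetic datasets in about a minute.  Initial values are the best
of ten feasible prior draws per chain — still over-dispersed across chains,
but avoiding pathological corners (e.g. `sigma2 > 10`).

Known limitation: occasional synthetic datasets (extreme depletion paths)
produce genuinely multimodal posteriors in `(R_max, q, z)`; a random-walk
sampler then under-mixes between modes and R-hat stays above 1.1 even at
10^5 iterations.  The convergence battery reports this honestly rather than
masking it.

## Convergence diagnostics

Gelman–Rubin (classical between/within PSRF with the degrees-of-freedom
adjustment; exactly identical chains give 1.0 and the estimate is floored at
1.0), Geweke (first 10% vs last 50% window means, variances from an AR
spectral-density-at-zero estimator with Yule-Walker fitting and AIC order
selection), the two-stage Heidelberger–Welch test (Cramér–von-Mises
stationarity stage with 10% block discards, then the half-width stage), and
the autocorrelation function at the thinned scale (flag at |ACF(1)| > 0.1).
The spectral estimator and both tests are written to match the classical R
reference implementations; the test suite pins their outputs to reference
values computed with R `coda` on fixture chains stored in the repository
(agreement to 1e-6, including the known inaccuracy of the truncated
Cramér–von-Mises series at extreme statistics).

## Removals reconstruction

Cumulative harvest exports, reported at ~5-year intervals, are fitted with a
Gompertz curve `C(t) = A exp(-exp(-k (t - t0)))` under additive normal error
(parameter names `A`, `k`, `t0` are this package's own; only the curve
family is given by the record).  The fit is multi-start least squares
(`scipy.optimize.least_squares`, grid over `k` and `t0`, `A` initialized at
the largest cumulative value); annual harvests are consecutive-year
differences of the fitted curve, clamped at zero with a logged warning, and
isolated single-rookery harvest events enter as configured additive pulses.
A flat export series raises an explicit error naming the degenerate best
candidate.  Bycatch is `M_t = Σ_i rate_i(mode) · E_it` over nine fishing
types under three rate assumptions (Total/Average/Maximum catch per
boat-day), zero outside 1989–2013 unless effort rows exist.

## Abundance index assembly

Three fixed regressions (re-fittable, but constants by default) reconstruct
the total index from partial counts: non-pups from pups (`y = 1.1152 x`),
non-key-rookery animals from the four key ("4B") rookeries' total
(`ln y = -19.982 + 3.1236 ln x`, output excluding the 4B animals, then
summed), and the two-region total from the northern region (`y = 1.815 x`).
Composition order for pup-only years: pups → non-pups → 4B total → non-4B
expansion → sum → regional scaling.  Each survey year carries flags naming
which corrections apply; years whose 4B rookeries were not all surveyed
yield a missing value.  The default coverage table reproduces the historical
pattern: 24 usable years between 1972 and 2015, with gaps at 1986–88, 1993,
2002–04, 2010–11 and 2013.  The index is reported in thousands.

## Synthetic-data generator

The generator emulates the study's data regime with known truth so the whole
pipeline can be validated end to end.  Defaults:

- **truth**: `R_max = 0.055`, `K = 319.3`, `z = 5.817`, `q = 0.566`,
  `sigma2 = 0.084`, `tau2 = 0.098` — the posterior medians estimated for the
  study population (non-linear variant, total-catch bycatch), so synthetic
  scenarios live in the empirically relevant regime;
- **harvest**: Gompertz pulse over 1929–1960 with asymptote 460,000, rate
  0.18/yr, inflection 1939.5, plus small configured pulses in 1921 and
  1938–40.  This asymptote is chosen so the *deterministic* trajectory
  reproduces the qualitative history: collapse below 10% of `K` by the early
  1960s and recovery to ~60% of `K` by 2013.  (A pulse at the export-record
  scale, peak ≈ 17,900/yr, cannot deplete a 319-thousand population in this
  model — production outruns it; the export-scale reconstruction is
  exercised separately with an explicit asymptote of 195,400.)
- **bycatch**: nine fishing types with total-catch rates 0.002–0.02 animals
  per boat-day (two types zero), average rates 0.55× and maximum rates 1.8×
  the total-catch rates, effort ramping 6,000→13,000 days/type/yr with
  lognormal jitter — annual totals span ≈ 215–1,600 animals across the three
  assumptions, matching the reconstructed fishery record;
- **observations**: the historical 24-year survey pattern, lognormal noise
  `tau2 = 0.098`; the final survey year (2015) is generated but excluded
  from fitting, mirroring its held-out role;
- **seeding**: one master seed expands into per-component substreams
  (states, observations, exports, effort) via `SeedSequence` spawn keys, so
  adding a component never shifts existing draws; scenarios are
  byte-identical given (config, seed).

**Feasibility conditioning.** Under the default truth the multiplicative
process noise (`sigma ≈ 0.29`/yr) compounded over a 116-year horizon with a
deep harvest pulse drives ~95% of unconditional state paths through zero.
`simulate_states` raises on such paths (synthetic truth must be feasible);
`generate_scenario` retries with deterministic per-attempt substreams and
records the accepted attempt.  Generated scenarios are therefore draws from
the state process *conditioned on full-path positivity*.  The practical
consequence: realized process deviations are not exactly i.i.d.
Normal(0, sigma2) — they are the feasible subset — which slightly favours
upward deviations during the depletion trough.  Despite this mild
misspecification, the suite's 20-replicate recovery study finds 95%
credible-interval coverage of `R_max`, `q` and `K` well above its 80%
threshold, and the observation-noise distribution (which is not
conditioned) passes a KS test at n = 10^4.

What the generator does **not** emulate: age/sex structure, spatial
structure among rookeries, observer error in the effort/rate tables,
time-varying carrying capacity, and real survey-count integerness.  Passing
tests therefore certify the estimation machinery under the model's own
assumptions, not robustness to structural misspecification.

## Evaluation

- **DIC** with `pV = Var(D)/2` (sample variance, n−1 denominator) as the
  complexity penalty; deviance is `-2 ×` the observation log-likelihood with
  latent states treated as parameters (pD is deliberately not implemented —
  it is unstable for this model class).  `ΔDIC < 2` is flagged as no
  meaningful difference.
- **Posterior predictive check**: replicate survey sets simulated from the
  observation equation at each retained draw; default discrepancy is the
  χ²-type sum of squared standardized log residuals (pluggable registry).
  Replicate noise is attached in a content-sorted draw order so the p-value
  is invariant to how chains and draws happen to be arranged.  Reasonable
  fit: 0.1 < p < 0.9.
- **Standardized residuals**: `(ln I_t − ln(q K P_t))/tau` averaged over
  draws, per survey year.
- **Projection**: per-draw forward simulation with fresh process and
  observation noise; brackets that would go non-positive under supplied
  future removals are floored at 1e-6 and counted per year.
- **Sensitivity**: one full refit per preset (identical data, chain design
  and seed policy), posterior-median deltas against the base case, quantile
  table (2.5/25/50/75/97.5%) per preset.

## Numerical choices

- Positivity handling differs by role, deliberately: the *generator* raises
  on an infeasible schedule (truth must be feasible), *inference* returns
  `-inf` (proposal rejected, posterior stays proper), *projection* floors
  and flags (a forecast must produce a number).
- NaN brackets from floating overflow (huge deviations × large `z`) are
  treated as infeasible, not silently accepted.
- Gompertz fitting optimizes `log A` with bounds; degenerate fits (rate at
  its lower bound, or flat input) raise with the best candidate attached.
- The Gelman-Rubin estimate is floored at 1.0 (the unfloored classical
  estimator gives values slightly below 1 for identical chains).
- Problem sizes in tests and the acceptance script — 20 fit replicates at
  the scaled design, 12 in the recovery study of the acceptance script,
  single fits at one-tenth of the full design — were chosen as the smallest
  sizes at which the Monte-Carlo error of each check is comfortably below
  its decision threshold.
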