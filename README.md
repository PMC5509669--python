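# otaria

Bayesian state-space surplus-production analysis of a depleted and
recovering South American sea lion (*Otaria flavescens*) population, built
as a reusable, fully tested pipeline: removals reconstruction, survey
correction, MCMC model fitting, model comparison, projection and prior
sensitivity — plus a seeded synthetic-data generator that reproduces the
study's data regime so every stage can be validated against known truth.

## The problem

Northern and central Patagonia's sea lion population was decimated by a
commercial leather harvest (1929–1960) and has been recovering since, under
low-level fisheries bycatch.  The only harvest record is cumulative export
totals at ~5-year intervals; abundance is observed through shore counts
that rarely cover the whole coast and skip years entirely.  The questions:
how fast can the population grow when depressed (R_max), how large was it
before exploitation (K), and does density dependence act linearly or only
near carrying capacity (shape parameter z)?

## The model

Latent dynamics (relative abundance P_t = N_t/K, years 1900–2013):

    P_{1900..1928} = e^{U_1}                                 (pre-harvest equilibrium)
    P_t = (P_{t-1} + R_max P_{t-1}(1 - P_{t-1}^z)
           - H_{t-1}/K - M_{t-1}/K) e^{U_t},   U_t ~ N(0, σ²)

Observations (corrected survey index, thousands of animals):

    I_t = q K P_t e^{V_t},   V_t ~ N(0, τ²)

Six variants are fitted — {linear z=1, non-linear z estimated} × {three
bycatch series TC/AC/MC} — by adaptive Metropolis-within-Gibbs MCMC
(numba-compiled) under vague priors, and compared by DIC = mean(D) + pV
with pV = Var(D)/2.  Convergence is checked with Gelman–Rubin, Geweke,
Heidelberger–Welch and autocorrelation diagnostics whose implementations
match the classical R `coda` procedures to 1e-6.  See `docs/methods.md`
for the full specification.

## Worked example

Reconstruct annual harvests from cumulative export records
(`examples/02_reconstruct_removals.py`):

```
Gompertz fit: asymptote 194,491, rate 0.243/yr, inflection 1939.5, residual SD 1,987
annual harvest peaks at 17,376 animals in 1940
bycatch TC: 418-885 animals/yr over 1989-2013
bycatch AC: 230-486 animals/yr over 1989-2013
bycatch MC: 752-1,592 animals/yr over 1989-2013
```

The sigmoid's inflection year dates the harvest peak, and its
consecutive-year differences recover the annual removals (peak ≈ 17,400
animals/yr around 1940) that only survive in five-yearly cumulative form.

Fit the model to a synthetic scenario with known truth
(`examples/04_fit_model.py`, ~1 minute):

```
posterior summary (K and the index in thousands of animals):
               mean        sd      2.5%    median      97.5%
r_max        0.0624    0.0318    0.0217    0.0553     0.1487
k          598.3663  395.5133  182.0772  493.9056  1647.9748
z            2.5951    2.0759    0.1930    1.9794     8.2069
q            0.4916    0.1997    0.1436    0.4805     0.8863
sigma2       0.1487    0.0606    0.0671    0.1369     0.2984
tau2         0.1610    0.0605    0.0799    0.1486     0.3128

true values: ModelParams(r_max=0.055, k=319.3, z=5.817, q=0.566, sigma2=0.084, tau2=0.098)
```

The posterior median of R_max (0.0553) recovers the true growth rate; K is
weakly identified (wide interval containing the truth) — exactly the
pattern real survey data produce, where the growth phase pins R_max and q
but the never-observed pristine abundance barely constrains K.

Other examples: scenario generation (`01`), survey-index assembly (`03`),
six-variant DIC comparison (`05`), projection and prior sensitivity (`06`).
A thin CLI wraps the pipeline: `otaria simulate`, `otaria reconstruct`,
`otaria fit`, `otaria evaluate`, `otaria project`, `otaria all --config
run.yaml`.

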