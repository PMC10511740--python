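# Methods

## Model and assumptions

The natural history of multiple myeloma is represented as a
closed birth cohort moving through four states — healthy (H), MGUS,
MM, dead (D) — under age-varying hazards, one cohort per gender × race
stratum (male/female × NHW/NHB; male NHW is the covariate reference).
The model assumes: (i) every MM case passes through MGUS; (ii) MGUS
onset and progression hazards are log-linear in raw age in years (the
progression hazard additionally log-quadratic, letting risk peak and
then decline); (iii) gender and race act as age-constant rate
multipliers e^β; (iv) no recovery from MGUS, and no intermediate
smoldering-myeloma state; (v) a single cross-sectional calibration —
no calendar-period or cohort effects.

Mortality is exogenous: life-table rates μ_H(a,s,r), piecewise
constant on integer-age years with ages beyond the last tabulated age
reusing the last value; MGUS mortality a gender-specific multiple of
μ_H (1.25 men, 1.11 women; both 1 in the no-MGUS-effect sensitivity
variant); MM mortality an age-constant per-stratum rate, the
least-squares slope of log survival through the origin fitted to
registry survival curves (an individual-level maximum-likelihood fit
is out of scope).

## Calibration

The two data types multiply into one likelihood with no relative
weight. Binned MGUS-positive counts are binomial with success
probability the population-weighted mean of the alive-conditioned
model prevalence over the bin's integer ages (inclusive endpoints);
the binomial coefficient is dropped everywhere, consistently also in
the DIC. Binned MM incidence enters through its logarithm, normal
with mean log of the weighted model incidence and estimated variance
τ²; incidence is converted from per-100,000 person-years to per
person-year on read, and non-positive rows (log undefined) are
excluded with a logged count. Priors are independent uniforms:
γ ∈ [−20, 0], β_MGUS,a ∈ [0, 1], β_MM,a and β_MM,a² ∈ [−15, 1],
gender/race coefficients ∈ [−15, 5], τ² ∈ [0, 100].

The sampler is a joint adaptive random-walk Metropolis: multivariate
normal proposals with covariance 2.38²/d times the running empirical
chain covariance (plus a small diagonal jitter), and a global
log-scale nudged toward a 0.234 acceptance rate. Adaptation runs only
during burn-in and is frozen afterwards, so retained draws come from a
fixed-kernel chain. The full protocol is 1,000,000 iterations, 500,000
burn-in, thinning 50, five chains (retained count
(n − burn-in)/thin per chain, validated to divide exactly; note that
pooling five such chains yields 50,000 draws, whereas some published
figure captions cite 50,010 — the formula here is authoritative).
Convergence requires Gelman–Rubin < 1.1 per parameter, computed from
the classic between/within-chain variance ratio
sqrt(((n−1)/n·W + B/n)/W).

**Initialization.** Chains start overdispersed around a posterior mode
located by Nelder–Mead restarted from the best of 200 prior draws and
re-seeded at its own endpoint until it stalls; τ² is profiled out
analytically during the search (its conditional mode is the mean
squared log-incidence residual), which removes the flat plateau where
an inflated τ² absorbs incidence misfit and traps a naive joint
optimization. The initial proposal covariance and the overdispersion
shape (spread factor 2, redrawn until the posterior is finite) are the
inverse finite-difference Hessian at the mode, repaired and inverted
in correlation scale because the curvatures span ~7 orders of
magnitude across parameters. This was a genuinely open
design point: with pure uniform-prior starts the posterior — which
occupies a ~10⁻¹⁰ fraction of the prior box — is unreachable within
the desk-scale chain lengths used here (measured acceptance ~0.003 and
Gelman–Rubin ≫ 1.1), while mode-centered overdispersed starts give
acceptance ≈ 0.234 and Gelman–Rubin ≈ 1.00 at 60,000 iterations.
Uniform-prior initialization remains available
(`McmcSettings(init_strategy="prior")`) for long-chain runs.

## Numerical choices

- **Integration.** Fixed-step classical RK4 on an age grid from 0 to
  99 years, default step 0.1 yr, configurable; the step must divide
  one year exactly so every step lies inside a single integer-age year
  where mortality is constant (the smooth hazards are sampled on a
  half-step grid for the RK4 stage points). Cohorts start fully
  healthy at age 0. Accuracy is guarded by tests: halving the step
  moves no state by more than 1e-6, and proportions sum to one within
  1e-9.
- **Inadmissible parameters.** Vectors whose hazard exponent exceeds
  e³ ≈ 20/yr anywhere on the grid are assigned −∞ log-posterior: such
  rates are epidemiologically absurd and would destabilize the
  fixed-step integrator. Zero weighted prevalence with a positive
  observed count (and symmetrically prevalence 1 with y < n) also
  yields −∞ rather than an exception.
- **Dwell time.** The competing-risk integrals use a cumulative
  trapezoid for the exit hazard and Simpson's rule for the moments on
  a 0.1-yr lag grid, truncated at age 120 — with mortality clamped at
  its last tabulated value the surviving MGUS mass beyond 120 is
  ~1e-8 for onset ages ≤ 90, so extending the horizon changes nothing
  at the reported precision. Mortality during the dwell period is
  μ_MGUS, matching residence in the MGUS state.
- **DIC.** D̄ + p_D with D = −2 log-likelihood and
  p_D = D̄ − D(posterior mean), averaged over (at most 2,000 evenly
  thinned) pooled draws.
- **Posterior predictive.** Per retained draw, the model's bin
  predictions plus observation noise — binomial with the observed n
  for prevalence, lognormal with the draw's τ² for incidence —
  quantiled into 50% and 95% bands.
- **Model variant.** `quad_mm_age=off` pins β_MM,a² to zero and
  removes it from the sampled parameters and the prior normalization,
  for the DIC comparison of quadratic versus linear age effects.

## Synthetic data

The generator emulates the five real inputs with known truth. Its
default parameters are anchored to the published posterior medians —
MGUS onset 0.0012/yr at age 60 rising to 0.0034/yr at 80 (γ_MGUS =
−9.85, β_MGUS,a = 0.052), female multiplier 0.59 and NHB multiplier
2.0 on onset, progression peaking at age 71 (β_MM,a = 0.142,
β_MM,a² = −0.001, γ_MM = −9.24, peak rate ≈ 0.015/yr) with
multipliers 1.1 and 1.2 — these are targets distilled from a fitted
model, not the ground truth of the real surveys. Where the sources
print no value, defaults are chosen as a realistic US-like regime and
fixed: τ² = 0.01 (≈10% registry noise); Gompertz background mortality
μ_H = b·e^(0.085a) with b between 0.7e-4 (NHW women) and 1.4e-4 (NHB
men); MM mortality 0.18–0.22/yr (median survival ≈ 3–4 yr); a
population pyramid N(a) ∝ exp(−3.5e-4·a²) with NHW:NHB ≈ 6:1.
Prevalence bins are 5-yearly from 50 with an open 85+ bin and the
survey's published per-stratum tested counts (1735/1703/454/463)
allocated to bins proportional to population (per-bin counts are not
published); incidence bins are 5-yearly from 30 plus 85+. The
population table carries an aggregated 85+ row which the reader
disaggregates to ages 85–99 with an emitted reference distribution
(mass-preserving by construction); ages ≥ 100 carry no weight.

What the generator does **not** emulate: survey weights and
non-response, ascertainment bias, calendar-period trends, and the
cohort heterogeneity of real registries. Passing tests therefore
demonstrate that the estimator recovers the generating process under
the model's own assumptions — internal validity — not that those
assumptions hold for NHANES or SEER.

## Study sizes used by the tests and the reproduction script

Desk-scale analyses use 5 chains × 60,000 iterations, burn-in 30,000,
thin 10 (the full-protocol shape at reduced length); the DIC
replicates use 2 chains × 20,000, burn-in 10,000, thin 10, since only
a deviance summary is needed. The recovery study runs ten independent
generate-and-fit replicates at the survey-scale tested counts; the
event-simulation oracle uses 10⁶ individuals; dwell-time posteriors
subsample at most 2,000 (reported tables) or 1,000 (validation runs)
draws.

## Known limitations

- No smoldering-myeloma state; progression is a single MGUS→MM jump.
- The MCMC is a random-walk sampler; posteriors with much higher
  dimension or stronger multimodality would need gradient-based or
  tempered methods, which are out of scope.
- The exponential MM-survival fit ignores treatment-era and
  age-at-diagnosis structure, as in the source mortality construction.
- Credible-interval coverage claims are calibrated on the generator's
  regime; heavy model misspecification (e.g., real period effects)
  would not be detected by these tests.
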