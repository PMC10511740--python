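# mmnathist — natural history of multiple myeloma

Multiple myeloma (MM) is always preceded by an asymptomatic precursor,
monoclonal gammopathy of undetermined significance (MGUS), yet MGUS is
rarely diagnosed, so the preclinical phase of MM cannot be observed
directly. `mmnathist` is a calibration-and-analysis pipeline for a
four-state cohort model (healthy → MGUS → MM → death) that infers the
hidden MGUS onset and progression rates from two population-level data
sources: age-binned MGUS prevalence from a screening survey and
age-binned MM incidence from a cancer registry. It is written for
epidemiologists and biostatisticians studying how age, gender, and
race/ethnicity (non-Hispanic white, NHW, vs non-Hispanic Black, NHB)
shape the burden of MM.

## Model

For a birth cohort of gender *s* and race *r*, the proportions
P_H, P_MGUS, P_MM, P_D evolve in age *a* as

    dP_H/da    = −(λ_MGUS + μ_H) P_H
    dP_MGUS/da = λ_MGUS P_H − (λ_MM + μ_MGUS) P_MGUS
    dP_MM/da   = λ_MM P_MGUS − μ_MM P_MM
    dP_D/da    = μ_H P_H + μ_MGUS P_MGUS + μ_MM P_MM

with log-linear hazards

    λ_MGUS(a,s,r) = exp(γ_MGUS + β_MGUS,a·a + β_MGUS,s·[female] + β_MGUS,r·[NHB])
    λ_MM(a,s,r)   = exp(γ_MM + β_MM,a·a + β_MM,a²·a² + β_MM,s·[female] + β_MM,r·[NHB])

Background mortality μ_H comes from life tables; μ_MGUS is 1.25×μ_H
for men and 1.11×μ_H for women; μ_MM is an age-constant rate per
stratum from an exponential fit to registry survival curves.
Prevalence and incidence are conditioned on the surviving fraction
(p = P/(1−P_D); i = λ·p of the at-risk state) and averaged over
observation age bins with population weights. Binned MGUS-positive
counts are binomial around the weighted prevalence; the log of binned
MM incidence is normal with variance τ² around the log weighted
incidence. The ten parameters (γ_MGUS, β_MGUS,a, β_MGUS,s, β_MGUS,r,
γ_MM, β_MM,a, β_MM,a², β_MM,s, β_MM,r, τ²) carry uniform priors and
are sampled by adaptive random-walk Metropolis; convergence is judged
by the Gelman–Rubin statistic and model variants compared by DIC.

From the fitted model the package computes the **preclinical dwell
time** — the time from MGUS onset to MM onset, conditional on
progressing before death — and the **lifetime MM probability** per
onset age and stratum, via the competing-risk integral
E[T | MM] = ∫ t λ_MM S(t) dt / ∫ λ_MM S(t) dt with
S(t) = exp(−∫ (λ_MM + μ_MGUS)).

A synthetic-data generator emulates all five inputs (prevalence
counts, incidence rates, life table, population with an open 85+ bin,
MM survival curves) from known parameters, so the whole pipeline is
testable end to end without external downloads.

## Worked example

```python
import numpy as np
from mmnathist import AgeGrid, ModelContext, McmcSettings, run_mcmc, \
    gelman_rubin, posterior_summary, dwell_time_posterior, STRATA
from mmnathist.synthetic import SyntheticDesign, generate_truth_curves, \
    sample_observations

design = SyntheticDesign(seed=1)            # survey-scale synthetic study
curves = generate_truth_curves(design)
prev, inc = sample_observations(curves, design)
ctx = ModelContext(design.mortality_schedule(), design.population_table(),
                   AgeGrid(), prev, inc)
chains = run_mcmc(ctx, McmcSettings(n_iterations=60_000, burn_in=30_000,
                                    thin=10, n_chains=5, seed=42))
print("max Gelman-Rubin:", round(max(gelman_rubin(chains)), 3))
j = chains.param_names.index("beta_mgus_s")
print("female MGUS multiplier:",
      [round(v, 2) for v in posterior_summary(chains, lambda t: np.exp(t[j]))])
r = dwell_time_posterior(chains, ctx, [50.0], [STRATA[0]])[0]
print(f"dwell at onset 50 (NHW men): {r.dwell_median:.1f} "
      f"({r.dwell_lo:.1f}-{r.dwell_hi:.1f}) yr")
```

prints

```
max Gelman-Rubin: 1.001
female MGUS multiplier: [0.58, 0.44, 0.78]
dwell at onset 50 (NHW men): 13.7 (12.6-14.8) yr
```

— the five chains agree (Gelman–Rubin ≈ 1), the 95% credible interval
for the female MGUS-onset multiplier recovers the generating value
0.59, and a 50-year-old NHW man who develops MGUS and eventually
progresses is expected to do so after about 14 years under the
generator's mortality regime.

The same pipeline is available as numbered drivers
(`analysis/01_simulate.py` … `05_predictive.py`, writing their tables
under `results/`) and as a CLI
(`mmnathist simulate|validate|fit|diagnose|dwell|summarize`).

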