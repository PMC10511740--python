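"""Desk-scale validation studies.

Self-contained experiments that exercise the whole pipeline on
synthetic data with known truth: integrator conservation and
step-refinement accuracy, analytic constant-hazard limits, agreement
with the individual-based event simulator, MCMC parameter recovery
with convergence diagnostics and posterior-predictive calibration, and
the DIC comparison of the quadratic- versus linear-age progression
models. Both the test suite and the reproduction script run these.
"""

from __future__ import annotations

import numpy as np

from .cohort import AgeGrid, MortalitySchedule, integrate_cohort
from .dwell import dwell_time_moments
from .inference import McmcSettings, dic, gelman_rubin, posterior_predictive, run_mcmc
from .likelihood import ModelContext
from .montecarlo import simulate_cohort, simulate_dwell_cohort
from .params import ParameterVector
from .strata import STRATA, Gender
from .synthetic import SyntheticDesign, generate_truth_curves, sample_observations

#: Scaled-down sampler protocols. The recovery protocol is the
#: full-protocol shape at desk scale (5 chains, half burn-in); the DIC
#: replicates use a lighter protocol since only the deviance summary
#: is needed.
RECOVERY_MCMC = dict(n_iterations=60_000, burn_in=30_000, thin=10, n_chains=5)
DIC_MCMC = dict(n_iterations=20_000, burn_in=10_000, thin=10, n_chains=2)

GENDER_RACE_PARAMS = ("beta_mgus_s", "beta_mgus_r", "beta_mm_s", "beta_mm_r")


def _plausible_parameters(rng: np.random.Generator) -> ParameterVector:
    """Random hazard parameters in the epidemiologically plausible
    region (all rates well below 1/yr)."""
    ages = np.arange(100.0)
    b1a = rng.uniform(0.0, 0.08)
    b2a = rng.uniform(0.0, 0.2)
    b2a2 = rng.uniform(-0.002, 0.0)
    peak_mm = float(np.max(b2a * ages + b2a2 * ages ** 2))
    return ParameterVector(
        gamma_mgus=rng.uniform(-12.0, -6.0) - 99.0 * b1a * rng.uniform(0.3, 1.0),
        beta_mgus_a=b1a, beta_mgus_s=rng.uniform(-1.0, 1.0),
        beta_mgus_r=rng.uniform(-1.0, 1.0),
        gamma_mm=rng.uniform(-12.0, -5.0) - peak_mm,
        beta_mm_a=b2a, beta_mm_a2=b2a2,
        beta_mm_s=rng.uniform(-1.0, 1.0), beta_mm_r=rng.uniform(-1.0, 1.0),
        tau2=rng.uniform(0.001, 1.0))


def conservation_study(seed: int = 0, n_draws: int = 100) -> dict:
    """Integrator sanity over random plausible parameters: proportions
    sum to one everywhere, and halving the step barely moves the
    states at integer ages."""
    rng = np.random.default_rng(seed)
    mortality = SyntheticDesign().mortality_schedule()
    max_dev = 0.0
    max_change = 0.0
    grid = AgeGrid(step=0.1)
    grid_half = AgeGrid(step=0.05)
    int_idx = slice(None, None, grid.steps_per_year)
    int_idx_half = slice(None, None, grid_half.steps_per_year)
    for k in range(n_draws):
        p = _plausible_parameters(rng)
        st = STRATA[k % 4]
        traj = integrate_cohort(p, mortality, grid, st)
        total = traj.p_h + traj.p_mgus + traj.p_mm + traj.p_d
        max_dev = max(max_dev, float(np.max(np.abs(total - 1.0))))
        fine = integrate_cohort(p, mortality, grid_half, st)
        for coarse_arr, fine_arr in ((traj.p_h, fine.p_h), (traj.p_mgus, fine.p_mgus),
                                     (traj.p_mm, fine.p_mm), (traj.p_d, fine.p_d)):
            max_change = max(max_change, float(np.max(np.abs(
                coarse_arr[int_idx] - fine_arr[int_idx_half]))))
    return {"max_conservation_dev": max_dev, "max_step_halving_change": max_change,
            "n_draws": n_draws}


def analytic_limits_study() -> dict:
    """Constant-hazard closed forms: exponential decay of the healthy
    pool, and the competing-exponential dwell identities
    E[T | MM] = 1/(lambda+mu), P(MM) = lambda/(lambda+mu)."""
    st = STRATA[0]
    errs = []

    lam = 0.01
    p = ParameterVector(gamma_mgus=np.log(lam), gamma_mm=-np.inf)
    traj = integrate_cohort(p, MortalitySchedule.zero(), AgeGrid(0, 100, 0.1), st)
    errs.append(float(np.max(np.abs(traj.p_mgus - (1 - np.exp(-lam * traj.ages))))))

    p = ParameterVector(gamma_mm=np.log(0.1))
    dwell, prob = dwell_time_moments(p, MortalitySchedule.zero(), 0.0, st,
                                     max_age=400.0)
    errs += [abs(dwell - 10.0), abs(prob - 1.0)]

    mort = MortalitySchedule(mu_h={(a, s): 0.05 for a in range(100) for s in STRATA},
                             mgus_multiplier={Gender.male: 1.0, Gender.female: 1.0})
    p = ParameterVector(gamma_mm=np.log(0.05))
    dwell, prob = dwell_time_moments(p, mort, 0.0, st, max_age=500.0)
    errs += [abs(dwell - 10.0), abs(prob - 0.5)]
    return {"max_analytic_err": float(max(errs))}


def mc_oracle_study(seed: int = 0, n_individuals: int = 1_000_000) -> dict:
    """Deterministic trajectories and dwell moments versus the
    individual-based event simulator, in Monte-Carlo standard errors."""
    design = SyntheticDesign()
    truth = design.truth
    mortality = design.mortality_schedule()
    record_ages = np.array([50.0, 70.0, 90.0])
    max_z = 0.0
    for k, st in enumerate(STRATA[:2]):
        traj = integrate_cohort(truth, mortality, AgeGrid(), st)
        samp = simulate_cohort(truth, mortality, st, record_ages,
                               n_individuals=n_individuals, seed=seed + k)
        det = np.array([traj.at(a) for a in record_ages])
        se = np.maximum(samp.standard_errors(), 1e-12)
        max_z = max(max_z, float(np.max(np.abs(samp.proportions - det) / se)))

    max_z_dwell = 0.0
    for k, onset in enumerate((50.0, 75.0)):
        det_dwell, det_prob = dwell_time_moments(truth, mortality, onset, STRATA[0])
        mc = simulate_dwell_cohort(truth, mortality, STRATA[0], onset,
                                   n_individuals=n_individuals, seed=seed + 10 + k)
        max_z_dwell = max(max_z_dwell,
                          abs(mc.mean_dwell - det_dwell) / mc.se_dwell,
                          abs(mc.prob_mm - det_prob) / mc.se_prob)
    return {"max_z_cohort": max_z, "max_z_dwell": float(max_z_dwell),
            "n_individuals": n_individuals}


def _fit_synthetic(data_seed: int, mcmc_seed: int, mcmc: dict,
                   quad_mm_age: bool = True, design: SyntheticDesign | None = None):
    design = design if design is not None else SyntheticDesign(seed=data_seed)
    curves = generate_truth_curves(design)
    prev, inc = sample_observations(curves, design, seed=data_seed)
    context = ModelContext(design.mortality_schedule(), design.population_table(),
                           AgeGrid(), prev, inc, quad_mm_age=quad_mm_age)
    settings = McmcSettings(seed=mcmc_seed, **mcmc)
    chains = run_mcmc(context, settings)
    return design, context, chains


def recovery_study(seed: int = 0, n_seeds: int = 10, mcmc: dict | None = None) -> dict:
    """Fit NHANES-scale synthetic data for several seeds and record,
    per seed: whether the 95% credible intervals cover all four
    gender/race coefficients, the maximum Gelman-Rubin statistic, and
    the fraction of observation bins inside the 95% posterior
    prediction interval."""
    mcmc = mcmc or RECOVERY_MCMC
    rng = np.random.default_rng(seed)
    fit_seeds = rng.integers(0, 2 ** 31 - 1, size=(n_seeds, 2))
    per_seed = []
    for s in range(n_seeds):
        design, context, chains = _fit_synthetic(int(fit_seeds[s, 0]),
                                                 int(fit_seeds[s, 1]), mcmc)
        pooled = chains.pooled()
        truth = design.truth.to_array()
        covered = {}
        for name in GENDER_RACE_PARAMS:
            j = chains.param_names.index(name)
            lo, hi = np.quantile(pooled[:, j], [0.025, 0.975])
            covered[name] = bool(lo <= truth[context.active[j]] <= hi)
        rhat = gelman_rubin(chains)
        bands = posterior_predictive(chains, context, seed=int(fit_seeds[s, 0]),
                                     max_draws=1000, require_converged=False)
        obs_prev = np.array([o.y / o.n for o in context.prev_obs])
        obs_inc = np.array([o.x for o in context.inc_obs])
        per_seed.append({
            "covered": covered,
            "all_covered": all(covered.values()),
            "max_rhat": float(np.max(rhat)),
            "predictive_coverage": bands.coverage_95(obs_prev, obs_inc),
            "n_bins": len(context.prev_obs) + len(context.inc_obs),
        })
    return {
        "per_seed": per_seed,
        "n_seeds": n_seeds,
        "n_covered": sum(r["all_covered"] for r in per_seed),
        "max_rhat": max(r["max_rhat"] for r in per_seed),
        "mean_predictive_coverage": float(np.mean(
            [r["predictive_coverage"] for r in per_seed])),
    }


def dic_study(seed: int = 0, n_reps: int = 10, mcmc: dict | None = None) -> dict:
    """Replicate the model-comparison experiment: data generated with a
    negative quadratic age term; DIC should prefer the quadratic model
    over the linear variant."""
    mcmc = mcmc or DIC_MCMC
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=(n_reps, 3))
    results = []
    for r in range(n_reps):
        data_seed = int(rep_seeds[r, 0])
        _, ctx_q, chains_q = _fit_synthetic(data_seed, int(rep_seeds[r, 1]), mcmc,
                                            quad_mm_age=True)
        _, ctx_l, chains_l = _fit_synthetic(data_seed, int(rep_seeds[r, 2]), mcmc,
                                            quad_mm_age=False)
        dic_q = dic(chains_q, ctx_q.log_likelihood, max_draws=1000).dic
        dic_l = dic(chains_l, ctx_l.log_likelihood, max_draws=1000).dic
        results.append({"dic_quadratic": dic_q, "dic_linear": dic_l,
                        "quadratic_preferred": bool(dic_q < dic_l)})
    return {"per_rep": results, "n_reps": n_reps,
            "n_quadratic_preferred": sum(r["quadratic_preferred"] for r in results)}
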