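"""Observation models, priors, and the posterior kernel.

Two data types inform the fit. Age-binned MGUS prevalence counts are
binomial: y successes among n tested against the population-weighted
model prevalence of the bin (the binomial coefficient, constant in the
parameters, is omitted throughout, including in the DIC). Age-binned
MM incidence rates are lognormal: log x is normal around the log of
the population-weighted model incidence with variance tau^2. The two
likelihoods multiply unweighted; priors are independent uniforms.

:class:`ModelContext` packs observations, demography and grid into
plain arrays for the compiled kernel so the posterior can be evaluated
~10^6 times during MCMC. The module-level functions are the readable
reference path over the public cohort API; tests hold the two routes
together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .cohort import AgeGrid, MortalitySchedule, bin_weighted_summary, integrate_cohort
from .demography import PopulationTable
from .params import N_PARAMS, PARAM_NAMES, QUAD_MM_INDEX, ParameterVector, PriorSpec
from .strata import STRATA, StratumKey

__all__ = [
    "PrevalenceObservation",
    "IncidenceObservation",
    "ModelContext",
    "log_prior",
    "log_lik_prevalence",
    "log_lik_incidence",
    "log_posterior",
]

logger = logging.getLogger(__name__)

#: SEER-style incidence rates are reported per 100,000 person-years;
#: the model works per person-year.
PER_100K = 1.0e5


@dataclass(frozen=True)
class PrevalenceObservation:
    """MGUS-positive count y among n tested, one age bin and stratum."""

    a_lo: int
    a_hi: int
    stratum: StratumKey
    y: int
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.y <= self.n:
            raise ValueError(f"need 0 <= y <= n, got y={self.y}, n={self.n}")
        if self.a_lo > self.a_hi:
            raise ValueError("a_lo must not exceed a_hi")


@dataclass(frozen=True)
class IncidenceObservation:
    """MM incidence per person-year, one age bin and stratum."""

    a_lo: int
    a_hi: int
    stratum: StratumKey
    x: float

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError("incidence must be positive to enter the likelihood")
        if self.a_lo > self.a_hi:
            raise ValueError("a_lo must not exceed a_hi")


class ModelContext:
    """Everything needed to score a parameter vector against the data.

    Packs the mortality schedule, population weights, age grid and the
    two observation tables into kernel-ready arrays. The model variant
    ``quad_mm_age=False`` drops the quadratic MM age coefficient: it is
    pinned to zero and removed from the sampled (active) parameters and
    from the prior normalization.
    """

    def __init__(self, mortality: MortalitySchedule, population: PopulationTable,
                 grid: AgeGrid, prev_obs: Sequence[PrevalenceObservation],
                 inc_obs: Sequence[IncidenceObservation],
                 prior: PriorSpec | None = None, quad_mm_age: bool = True):
        self.mortality = mortality
        self.population = population
        self.grid = grid
        self.prev_obs = list(prev_obs)
        self.inc_obs = list(inc_obs)
        self.prior = prior if prior is not None else PriorSpec()
        self.quad_mm_age = quad_mm_age

        if grid.age_start != 0:
            # cohorts are born healthy; a later start would need an
            # explicit initial state
            raise ValueError("fitting context requires the grid to start at age 0")

        if quad_mm_age:
            self.active = np.arange(N_PARAMS, dtype=np.int64)
        else:
            self.active = np.array(
                [i for i in range(N_PARAMS) if i != QUAD_MM_INDEX], dtype=np.int64)
        self.active_names = [PARAM_NAMES[i] for i in self.active]
        self.n_active = len(self.active)

        lo_full = self.prior.lower()
        hi_full = self.prior.upper()
        self._logprior_const = float(
            -np.sum(np.log(hi_full[self.active] - lo_full[self.active])))

        n_int = grid.n_years + 1
        offset = int(grid.age_start)
        fem = np.array([1.0 if s.is_female else 0.0 for s in STRATA])
        nhb = np.array([1.0 if s.is_nhb else 0.0 for s in STRATA])
        mu_h_step, mu_g_step, mu_mm = mortality.step_arrays(grid)

        pv_str = np.array([o.stratum.index for o in self.prev_obs], dtype=np.int64)
        pv_y = np.array([float(o.y) for o in self.prev_obs])
        pv_n = np.array([float(o.n) for o in self.prev_obs])
        Wp = np.zeros((len(self.prev_obs), n_int))
        for r, o in enumerate(self.prev_obs):
            Wp[r] = population.weight_vector((o.a_lo, o.a_hi), o.stratum, offset, n_int)

        iv_str = np.array([o.stratum.index for o in self.inc_obs], dtype=np.int64)
        iv_logx = np.array([np.log(o.x) for o in self.inc_obs])
        Wi = np.zeros((len(self.inc_obs), n_int))
        for r, o in enumerate(self.inc_obs):
            Wi[r] = population.weight_vector((o.a_lo, o.a_hi), o.stratum, offset, n_int)

        self._pbar_buf = np.empty(len(self.prev_obs))
        self._ibar_buf = np.empty(len(self.inc_obs))
        self.packed = (
            lo_full, hi_full, self._logprior_const,
            grid.half_ages, grid.half_ages ** 2,
            mu_h_step, mu_g_step, mu_mm,
            fem, nhb, grid.steps_per_year, grid.n_years, grid.step,
            pv_str, pv_y, pv_n, Wp,
            iv_str, iv_logx, Wi,
        )

    # -- vector plumbing ---------------------------------------------------

    def full_vector(self, theta_active: np.ndarray) -> np.ndarray:
        """Embed an active-parameter vector into the full 10-vector
        (inactive coefficients pinned to zero... except tau2 which is
        always active)."""
        theta_active = np.asarray(theta_active, dtype=float)
        if theta_active.shape != (self.n_active,):
            raise ValueError(f"expected {self.n_active} active parameters")
        full = np.zeros(N_PARAMS)
        full[self.active] = theta_active
        return full

    def active_vector(self, theta_full: np.ndarray) -> np.ndarray:
        return np.asarray(theta_full, dtype=float)[self.active]

    def _sanitize(self, theta) -> np.ndarray:
        if isinstance(theta, ParameterVector):
            theta = theta.to_array()
        theta = np.ascontiguousarray(theta, dtype=float)
        if theta.shape == (self.n_active,) and self.n_active != N_PARAMS:
            theta = self.full_vector(theta)
        if theta.shape != (N_PARAMS,):
            raise ValueError(f"expected a {N_PARAMS}- or {self.n_active}-vector")
        if not self.quad_mm_age:
            theta = theta.copy()
            theta[QUAD_MM_INDEX] = 0.0
        return theta

    # -- evaluation --------------------------------------------------------

    def log_posterior(self, theta) -> float:
        lp, _ = _kernels.model_eval(self._sanitize(theta), *self.packed,
                                    self._pbar_buf, self._ibar_buf)
        return float(lp)

    def log_likelihood(self, theta) -> float:
        """Joint data log-likelihood (binomial + lognormal), the
        quantity whose -2x enters the DIC."""
        _, ll = _kernels.model_eval(self._sanitize(theta), *self.packed,
                                    self._pbar_buf, self._ibar_buf)
        return float(ll)

    def predicted_bins(self, theta) -> tuple[np.ndarray, np.ndarray]:
        """Model-predicted (weighted prevalence per prevalence row,
        weighted incidence per person-year per incidence row)."""
        lp, _ = _kernels.model_eval(self._sanitize(theta), *self.packed,
                                    self._pbar_buf, self._ibar_buf)
        if not np.isfinite(lp):
            raise ValueError("model prediction undefined for this parameter vector")
        return self._pbar_buf.copy(), self._ibar_buf.copy()

    def draw_initial(self, rng: np.random.Generator, max_tries: int = 100_000) -> np.ndarray:
        """Uniform prior draw redrawn until the posterior is finite."""
        lo = self.prior.lower()
        hi = self.prior.upper()
        for _ in range(max_tries):
            full = lo + (hi - lo) * rng.random(N_PARAMS)
            if not self.quad_mm_age:
                full[QUAD_MM_INDEX] = 0.0
            if np.isfinite(self.log_posterior(full)):
                return full
        raise RuntimeError("no finite-posterior initial point found in the prior box")


# ---------------------------------------------------------------------------
# Readable reference path (slow; mirrors the kernel term by term)
# ---------------------------------------------------------------------------


def log_prior(params: ParameterVector | np.ndarray, spec: PriorSpec) -> float:
    """Log density of the independent-uniform prior box; -inf outside."""
    theta = params.to_array() if isinstance(params, ParameterVector) else np.asarray(params)
    if not spec.contains(theta):
        return -np.inf
    return spec.log_density()


def _per_age_curves(params: ParameterVector, context: ModelContext):
    """Per-integer-age alive-conditioned p_MGUS and i_MM by stratum."""
    from .cohort import mm_rate, state_prevalence

    grid = context.grid
    ages = np.arange(int(grid.age_start), int(grid.age_end) + 1)
    p_mgus: dict[StratumKey, dict[int, float]] = {}
    i_mm: dict[StratumKey, dict[int, float]] = {}
    for st in STRATA:
        traj = integrate_cohort(params, context.mortality, grid, st)
        pm: dict[int, float] = {}
        im: dict[int, float] = {}
        for a in ages:
            _, pg, _ = state_prevalence(traj, float(a))
            pm[int(a)] = pg
            im[int(a)] = mm_rate(params, float(a), st) * pg
        p_mgus[st] = pm
        i_mm[st] = im
    return p_mgus, i_mm


def log_lik_prevalence(obs: Sequence[PrevalenceObservation],
                       params: ParameterVector, context: ModelContext) -> float:
    """Binomial log-likelihood of binned MGUS prevalence counts."""
    p_mgus, _ = _per_age_curves(params, context)
    total = 0.0
    for o in obs:
        pbar = bin_weighted_summary(p_mgus[o.stratum], context.population,
                                    (o.a_lo, o.a_hi), o.stratum)
        if pbar <= 0.0:
            if o.y > 0:
                return -np.inf
        elif pbar >= 1.0:
            if o.y < o.n:
                return -np.inf
        else:
            total += o.y * np.log(pbar) + (o.n - o.y) * np.log1p(-pbar)
    return total


def log_lik_incidence(obs: Sequence[IncidenceObservation],
                      params: ParameterVector, context: ModelContext) -> float:
    """Lognormal log-likelihood of binned MM incidence rates."""
    if params.tau2 <= 0:
        raise ValueError("tau2 must be positive")
    _, i_mm = _per_age_curves(params, context)
    total = 0.0
    c = -0.5 * np.log(2.0 * np.pi * params.tau2)
    for o in obs:
        ibar = bin_weighted_summary(i_mm[o.stratum], context.population,
                                    (o.a_lo, o.a_hi), o.stratum)
        if ibar <= 0.0:
            return -np.inf
        z = np.log(o.x) - np.log(ibar)
        total += c - z * z / (2.0 * params.tau2)
    return float(total)


def log_posterior(params: ParameterVector, context: ModelContext) -> float:
    """Prior + both likelihoods; -inf outside the prior short-circuits
    without integrating the model."""
    lp = log_prior(params, context.prior)
    if not np.isfinite(lp):
        return -np.inf
    lp += log_lik_prevalence(context.prev_obs, params, context)
    if not np.isfinite(lp):
        return -np.inf
    lp += log_lik_incidence(context.inc_obs, params, context)
    return float(lp)


def convert_per_100k(rates) -> np.ndarray:
    """Per-100,000-person-year rates to per person-year."""
    return np.asarray(rates, dtype=float) / PER_100K


def filter_positive_incidence(rows: Sequence[dict]) -> tuple[list[dict], int]:
    """Drop zero/negative incidence rows (log undefined), with a logged
    warning; returns (kept rows, number excluded)."""
    kept = [r for r in rows if r["incidence_per_100k"] > 0]
    n_excluded = len(rows) - len(kept)
    if n_excluded:
        logger.warning("excluded %d zero/negative incidence rows", n_excluded)
    return kept, n_excluded
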