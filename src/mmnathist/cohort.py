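"""Hazards and forward integration of a birth cohort.

The natural-history model tracks the proportions of a gender x race
birth cohort in four states — healthy (H), MGUS, MM, dead (D) — as a
system of linear ODEs in age:

    dP_H/da    = -(lambda_MGUS + mu_H) P_H
    dP_MGUS/da = lambda_MGUS P_H - (lambda_MM + mu_MGUS) P_MGUS
    dP_MM/da   = lambda_MM P_MGUS - mu_MM P_MM
    dP_D/da    = mu_H P_H + mu_MGUS P_MGUS + mu_MM P_MM

integrated with fixed-step RK4. Prevalence and incidence are
conditioned on the fraction of the cohort still alive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import _kernels
from .params import ParameterVector
from .strata import STRATA, Gender, StratumKey

__all__ = [
    "AgeGrid",
    "MortalitySchedule",
    "CohortTrajectory",
    "ExtinctCohortError",
    "mgus_rate",
    "mm_rate",
    "integrate_cohort",
    "state_prevalence",
    "state_incidence",
    "bin_weighted_summary",
]


class ExtinctCohortError(ValueError):
    """Alive-conditioned quantities are undefined once P_D reaches 1."""


@dataclass(frozen=True)
class AgeGrid:
    """Uniform integration grid over age, step an exact divisor of 1 yr.

    The divisibility requirement keeps every RK4 step inside one
    integer-age year, where background mortality is constant.
    """

    age_start: float = 0.0
    age_end: float = 99.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.age_end <= self.age_start:
            raise ValueError("age_end must exceed age_start")
        if abs(round(1.0 / self.step) * self.step - 1.0) > 1e-9:
            raise ValueError("step must divide 1 year exactly (e.g. 0.1, 0.25, 0.5)")
        if abs(self.age_start - round(self.age_start)) > 1e-9 or \
           abs(self.age_end - round(self.age_end)) > 1e-9:
            raise ValueError("age_start and age_end must be integers")

    @property
    def steps_per_year(self) -> int:
        return round(1.0 / self.step)

    @property
    def n_years(self) -> int:
        return round(self.age_end - self.age_start)

    @property
    def n_steps(self) -> int:
        return self.n_years * self.steps_per_year

    @property
    def ages(self) -> np.ndarray:
        return self.age_start + np.arange(self.n_steps + 1) * self.step

    @property
    def half_ages(self) -> np.ndarray:
        return self.age_start + np.arange(2 * self.n_steps + 1) * (self.step / 2.0)

    def index_of(self, age: float) -> int:
        idx = (age - self.age_start) / self.step
        r = round(idx)
        if abs(idx - r) > 1e-6 or r < 0 or r > self.n_steps:
            raise ValueError(f"age {age} is not on the grid")
        return int(r)

    def refined(self, factor: int) -> "AgeGrid":
        return AgeGrid(self.age_start, self.age_end, self.step / factor)


@dataclass
class MortalitySchedule:
    """Background, MGUS and MM mortality by age and stratum.

    mu_h holds per-integer-age all-cause rates (piecewise constant on
    [a, a+1)); ages beyond the last tabulated age reuse the last value.
    MGUS mortality is a gender-specific multiple of mu_h; MM mortality
    is an age-constant per-stratum rate from the exponential survival
    fit.
    """

    mu_h: Mapping[tuple[int, StratumKey], float]
    mgus_multiplier: Mapping[Gender, float] = field(
        default_factory=lambda: {Gender.male: 1.25, Gender.female: 1.11}
    )
    mu_mm: Mapping[StratumKey, float] = field(
        default_factory=lambda: {s: 0.0 for s in STRATA}
    )

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.mu_h.values()):
            raise ValueError("mortality rates must be non-negative")
        if any(v < 0 for v in self.mu_mm.values()):
            raise ValueError("MM mortality rates must be non-negative")
        self._max_age: dict[StratumKey, int] = {}
        for (age, st) in self.mu_h:
            self._max_age[st] = max(self._max_age.get(st, age), age)

    def mu_h_at(self, age: float, stratum: StratumKey) -> float:
        if age < 0:
            raise ValueError("age must be non-negative")
        a = int(np.floor(age))
        a = min(a, self._max_age[stratum])
        return float(self.mu_h[(a, stratum)])

    def mu_mgus_at(self, age: float, stratum: StratumKey) -> float:
        return self.mgus_multiplier[stratum.gender] * self.mu_h_at(age, stratum)

    def mu_mm_at(self, stratum: StratumKey) -> float:
        return float(self.mu_mm[stratum])

    def step_arrays(self, grid: AgeGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mu_h, mu_mgus) per stratum per step plus mu_mm per stratum,
        packed in canonical stratum order for the kernels."""
        n = grid.n_steps
        mu_h = np.empty((4, n))
        mu_g = np.empty((4, n))
        mu_m = np.empty(4)
        mid = grid.age_start + (np.arange(n) + 0.5) * grid.step
        for k, st in enumerate(STRATA):
            mu_h[k] = [self.mu_h_at(a, st) for a in mid]
            mu_g[k] = self.mgus_multiplier[st.gender] * mu_h[k]
            mu_m[k] = self.mu_mm_at(st)
        return mu_h, mu_g, mu_m

    @classmethod
    def zero(cls) -> "MortalitySchedule":
        """All-zero mortality (useful for analytic limits)."""
        mu = {(a, st): 0.0 for a in range(100) for st in STRATA}
        return cls(mu_h=mu, mgus_multiplier={Gender.male: 1.0, Gender.female: 1.0})


@dataclass
class CohortTrajectory:
    """State proportions of one stratum's birth cohort on an age grid."""

    grid: AgeGrid
    stratum: StratumKey
    p_h: np.ndarray
    p_mgus: np.ndarray
    p_mm: np.ndarray
    p_d: np.ndarray

    @property
    def ages(self) -> np.ndarray:
        return self.grid.ages

    def at(self, age: float) -> tuple[float, float, float, float]:
        i = self.grid.index_of(age)
        return (float(self.p_h[i]), float(self.p_mgus[i]),
                float(self.p_mm[i]), float(self.p_d[i]))


def _check_age(age) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    return age


def mgus_rate(params: ParameterVector, age, stratum: StratumKey):
    """Rate (per year) at which a healthy individual develops MGUS."""
    age = _check_age(age)
    expo = (params.gamma_mgus + params.beta_mgus_a * age
            + params.beta_mgus_s * stratum.is_female
            + params.beta_mgus_r * stratum.is_nhb)
    out = np.exp(expo)
    return float(out) if out.ndim == 0 else out


def mm_rate(params: ParameterVector, age, stratum: StratumKey):
    """Rate (per year) at which an MGUS-positive individual develops MM.

    Log-quadratic in age: with a negative quadratic coefficient the
    rate peaks at -beta_mm_a / (2 beta_mm_a2) and declines beyond.
    """
    age = _check_age(age)
    expo = (params.gamma_mm + params.beta_mm_a * age
            + params.beta_mm_a2 * age ** 2
            + params.beta_mm_s * stratum.is_female
            + params.beta_mm_r * stratum.is_nhb)
    out = np.exp(expo)
    return float(out) if out.ndim == 0 else out


def integrate_cohort(params: ParameterVector, mortality: MortalitySchedule,
                     grid: AgeGrid, stratum: StratumKey,
                     initial_state=None) -> CohortTrajectory:
    """Integrate the cohort ODEs forward with fixed-step RK4.

    initial_state is (P_H, P_MGUS, P_MM, P_D) at grid.age_start and
    must be a non-negative probability vector; default: everyone
    healthy.
    """
    if initial_state is None:
        init = np.array([1.0, 0.0, 0.0, 0.0])
    else:
        init = np.asarray(initial_state, dtype=float)
        if init.shape != (4,) or np.any(init < 0) or abs(init.sum() - 1.0) > 1e-9:
            raise ValueError("initial_state must be a length-4 probability vector")

    half = grid.half_ages
    lam1 = mgus_rate(params, half, stratum)
    lam2 = mm_rate(params, half, stratum)
    n = grid.n_steps
    mid = grid.age_start + (np.arange(n) + 0.5) * grid.step
    mu_h = np.array([mortality.mu_h_at(a, stratum) for a in mid])
    mu_g = mortality.mgus_multiplier[stratum.gender] * mu_h
    mu_m = mortality.mu_mm_at(stratum)

    out = np.empty((n + 1, 4))
    _kernels.rk4_cohort(lam1, 1.0, lam2, 1.0, mu_h, mu_g, mu_m,
                        n, grid.step, init, out)
    return CohortTrajectory(grid=grid, stratum=stratum,
                            p_h=out[:, 0], p_mgus=out[:, 1],
                            p_mm=out[:, 2], p_d=out[:, 3])


def state_prevalence(traj: CohortTrajectory, age: float) -> tuple[float, float, float]:
    """Alive-conditioned (p_H, p_MGUS, p_MM) at a grid age.

    Each compartment is divided by the surviving fraction 1 - P_D; p_H
    is computed as the complement so the three sum to one exactly.
    """
    ph, pg, pm, pd = traj.at(age)
    alive = 1.0 - pd
    if alive <= 0.0:
        raise ExtinctCohortError(f"cohort extinct at age {age}: prevalence undefined")
    p_mgus = pg / alive
    p_mm = pm / alive
    return 1.0 - p_mgus - p_mm, p_mgus, p_mm


def state_incidence(traj: CohortTrajectory, params: ParameterVector,
                    mortality: MortalitySchedule, age: float) -> tuple[float, float]:
    """Alive-conditioned incidence (i_MGUS, i_MM) per person-year:
    hazard times the prevalence of the at-risk state."""
    p_h, p_mgus, _ = state_prevalence(traj, age)
    i_mgus = mgus_rate(params, age, traj.stratum) * p_h
    i_mm = mm_rate(params, age, traj.stratum) * p_mgus
    return i_mgus, i_mm


def bin_weighted_summary(values: Mapping[int, float], population,
                         age_bin: tuple[int, int], stratum: StratumKey) -> float:
    """Population-weighted mean of per-age values over an inclusive
    integer-age bin: sum_a N(a) v(a) / sum_a N(a), a = a_lo..a_hi."""
    a_lo, a_hi = age_bin
    if a_hi < a_lo:
        raise ValueError("bin upper bound below lower bound")
    num = 0.0
    den = 0.0
    for a in range(int(a_lo), int(a_hi) + 1):
        n = population.count(a, stratum)
        num += n * values[a]
        den += n
    if den <= 0:
        raise ValueError(f"zero total population in bin [{a_lo}, {a_hi}]")
    return num / den
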