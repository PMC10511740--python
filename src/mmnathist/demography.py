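"""Mortality schedules and population weights from raw tables.

Three mortality schedules enter the cohort model: background
(life-table) mortality for healthy individuals, MGUS mortality as a
gender-specific multiple of background (1.25 for men, 1.11 for women),
and an age-constant MM mortality rate per stratum obtained by fitting
an exponential survival distribution to registry all-cause survival.
Population counts weight per-age model output into observation bins;
an open 85+ count is disaggregated to single ages 85-99 with a
reference age distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .strata import StratumKey

__all__ = [
    "PopulationTable",
    "SurvivalCurve",
    "build_mgus_mortality",
    "fit_exponential_survival",
    "disaggregate_open_age_bin",
]

#: Default MGUS mortality multipliers by gender label; a sensitivity
#: variant sets both to 1 (no MGUS effect on mortality).
DEFAULT_MGUS_MULTIPLIERS = {"male": 1.25, "female": 1.11}


@dataclass
class PopulationTable:
    """Per-integer-age, per-stratum person counts N(a, s, r)."""

    counts: Mapping[tuple[int, StratumKey], float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("population counts must be non-negative")

    def count(self, age: int, stratum: StratumKey) -> float:
        return float(self.counts.get((age, stratum), 0.0))

    def weight_vector(self, age_bin: tuple[int, int], stratum: StratumKey,
                      age_offset: int, n_ages: int) -> np.ndarray:
        """Normalized bin weights over a length-n_ages integer-age axis
        starting at age_offset (packing helper for the likelihood)."""
        w = np.zeros(n_ages)
        a_lo, a_hi = age_bin
        for a in range(int(a_lo), int(a_hi) + 1):
            j = a - age_offset
            if not 0 <= j < n_ages:
                raise ValueError(f"age {a} of bin {age_bin} outside the model age range")
            w[j] = self.count(a, stratum)
        tot = w.sum()
        if tot <= 0:
            raise ValueError(f"zero population in bin {age_bin} for {stratum.label()}")
        return w / tot


@dataclass
class SurvivalCurve:
    """All-cause survival S(t) of an MM cohort, as (time, fraction) points."""

    times: np.ndarray
    fractions: np.ndarray
    stratum: StratumKey | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.times.shape != self.fractions.shape or self.times.ndim != 1:
            raise ValueError("times and fractions must be matching 1-D arrays")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(self.fractions <= 0) or np.any(self.fractions > 1):
            raise ValueError("surviving fractions must lie in (0, 1]")
        order = np.argsort(self.times)
        if np.any(np.diff(self.fractions[order]) > 0):
            raise ValueError("surviving fraction must be non-increasing in time")


def build_mgus_mortality(mu_h: Mapping, gender: str,
                         multipliers: Mapping[str, float] | None = None) -> dict:
    """Scale a background mortality map into the MGUS schedule.

    Applies the gender's multiplier to every rate in ``mu_h`` (a map of
    arbitrary keys to rates). Multipliers are configurable; setting
    both to 1 reproduces the no-MGUS-mortality-effect variant.
    """
    mult_map = DEFAULT_MGUS_MULTIPLIERS if multipliers is None else multipliers
    if gender not in mult_map:
        raise ValueError(f"unknown gender label {gender!r}")
    m = mult_map[gender]
    if any(v < 0 for v in mu_h.values()):
        raise ValueError("mortality rates must be non-negative")
    return {k: m * v for k, v in mu_h.items()}


def fit_exponential_survival(curve: SurvivalCurve) -> float:
    """Least-squares exponential rate through the origin.

    Minimizes sum_t (log S(t) + mu t)^2, giving the closed form
    mu = -sum(t log S) / sum(t^2). Points at t = 0 carry no
    information (log S(0) = 0) and drop out naturally.
    """
    t = curve.times
    logs = np.log(curve.fractions)
    mask = t > 0
    if np.count_nonzero(mask) < 1 or len(np.unique(t[mask])) < 1:
        raise ValueError("need at least one point at t > 0")
    if np.all(curve.fractions >= 1.0):
        raise ValueError("degenerate fit: survival never drops below 1")
    mu = -float(np.sum(t[mask] * logs[mask]) / np.sum(t[mask] ** 2))
    if mu <= 0:
        raise ValueError("degenerate fit: non-decreasing survival curve")
    return mu


def disaggregate_open_age_bin(aggregate_count: float,
                              reference_distribution: Mapping[int, float]) -> dict[int, float]:
    """Split an open-ended (85+) population count across single ages.

    The reference distribution gives the assumed proportion of the
    aggregate at each age; proportions must be non-negative and sum to
    one. Mass is preserved exactly.
    """
    if aggregate_count < 0:
        raise ValueError("aggregate count must be non-negative")
    props = np.array(list(reference_distribution.values()), dtype=float)
    if np.any(props < 0):
        raise ValueError("reference proportions must be non-negative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("reference proportions must sum to 1")
    return {age: aggregate_count * p
            for age, p in reference_distribution.items()}
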