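"""The estimated parameter vector and its uniform prior box.

Ten quantities are estimated: for the MGUS-onset hazard an intercept,
an age slope, and female/NHB log-multipliers; for the MGUS->MM
progression hazard an intercept, linear and quadratic age terms, and
female/NHB log-multipliers; plus the variance tau^2 of log MM
incidence. Both hazards are log-linear in raw age (years):

    lambda_MGUS(a,s,r) = exp(gamma_MGUS + b_a*a + b_s*[female] + b_r*[NHB])
    lambda_MM(a,s,r)   = exp(gamma_MM + b_a*a + b_a2*a^2 + b_s*[female] + b_r*[NHB])
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

PARAM_NAMES: tuple[str, ...] = (
    "gamma_mgus",
    "beta_mgus_a",
    "beta_mgus_s",
    "beta_mgus_r",
    "gamma_mm",
    "beta_mm_a",
    "beta_mm_a2",
    "beta_mm_s",
    "beta_mm_r",
    "tau2",
)

N_PARAMS = len(PARAM_NAMES)

#: Index of the quadratic MM age coefficient, dropped by the
#: quad_mm_age=off model variant.
QUAD_MM_INDEX = PARAM_NAMES.index("beta_mm_a2")


@dataclass
class ParameterVector:
    gamma_mgus: float = 0.0
    beta_mgus_a: float = 0.0
    beta_mgus_s: float = 0.0
    beta_mgus_r: float = 0.0
    gamma_mm: float = 0.0
    beta_mm_a: float = 0.0
    beta_mm_a2: float = 0.0
    beta_mm_s: float = 0.0
    beta_mm_r: float = 0.0
    tau2: float = 1.0

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ParameterVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_PARAMS,):
            raise ValueError(f"expected a length-{N_PARAMS} vector, got shape {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr)))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


#: Default uniform prior bounds for each parameter (lower, upper).
DEFAULT_PRIOR_BOUNDS: dict[str, tuple[float, float]] = {
    "gamma_mgus": (-20.0, 0.0),
    "beta_mgus_a": (0.0, 1.0),
    "beta_mgus_s": (-15.0, 5.0),
    "beta_mgus_r": (-15.0, 5.0),
    "gamma_mm": (-20.0, 0.0),
    "beta_mm_a": (-15.0, 1.0),
    "beta_mm_a2": (-15.0, 1.0),
    "beta_mm_s": (-15.0, 5.0),
    "beta_mm_r": (-15.0, 5.0),
    "tau2": (0.0, 100.0),
}


@dataclass
class PriorSpec:
    """Independent uniform priors, one (lower, upper) box per parameter."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PRIOR_BOUNDS)
    )

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.bounds)
        if missing:
            raise ValueError(f"missing prior bounds for: {sorted(missing)}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name}: lower {lo} must be < upper {hi}")

    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in PARAM_NAMES])

    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in PARAM_NAMES])

    def contains(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower()) and np.all(theta <= self.upper()))

    def log_density(self) -> float:
        """Log density of the uniform box, valid inside the bounds."""
        return float(-np.sum(np.log(self.upper() - self.lower())))
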