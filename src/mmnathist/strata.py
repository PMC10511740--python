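"""Population strata: gender x race/ethnicity.

The model stratifies a US birth cohort by gender (male/female) and
race/ethnicity (non-Hispanic white, NHW; non-Hispanic Black, NHB).
Male NHW is the covariate reference level: the gender and race
coefficients enter the hazards as log-multipliers relative to it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Gender(str, enum.Enum):
    male = "male"
    female = "female"


class Race(str, enum.Enum):
    NHW = "NHW"
    NHB = "NHB"


@dataclass(frozen=True, order=True)
class StratumKey:
    """One gender x race stratum; exactly four exist."""

    gender: Gender
    race: Race

    @property
    def is_female(self) -> bool:
        return self.gender is Gender.female

    @property
    def is_nhb(self) -> bool:
        return self.race is Race.NHB

    @property
    def index(self) -> int:
        """Canonical position in the fixed stratum ordering."""
        return STRATA.index(self)

    def label(self) -> str:
        return f"{self.gender.value}_{self.race.value}"


# Canonical ordering used for all packed arrays: reference level first.
STRATA: tuple[StratumKey, ...] = (
    StratumKey(Gender.male, Race.NHW),
    StratumKey(Gender.female, Race.NHW),
    StratumKey(Gender.male, Race.NHB),
    StratumKey(Gender.female, Race.NHB),
)


def stratum_from_labels(gender: str, race: str) -> StratumKey:
    """Parse serialized labels ("male"/"female", "NHW"/"NHB")."""
    try:
        return StratumKey(Gender(gender), Race(race))
    except ValueError as exc:
        raise ValueError(f"unknown stratum labels gender={gender!r} race={race!r}") from exc
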