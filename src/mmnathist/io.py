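"""Reading, validating and writing the pipeline's tables.

All interchange is headered CSV. Schemas:

- life table: age, gender, race, mu_h (per year)
- population: age (integer or "85+"), gender, race, N
- reference distribution (for the open age bin): age, gender, race, proportion
- MM survival: time_years, surviving_fraction, gender, race
- prevalence: age_lo, age_hi, gender, race, y, n
- incidence: age_lo, age_hi, gender, race, incidence_per_100k

Genders are "male"/"female", races "NHW"/"NHB". Incidence is converted
to per person-year on read; zero-incidence rows are excluded with a
warning (their logarithm is undefined).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import AgeGrid, MortalitySchedule
from .demography import (DEFAULT_MGUS_MULTIPLIERS, PopulationTable, SurvivalCurve,
                         disaggregate_open_age_bin, fit_exponential_survival)
from .likelihood import (PER_100K, IncidenceObservation, ModelContext,
                         PrevalenceObservation)
from .params import DEFAULT_PRIOR_BOUNDS, PriorSpec
from .strata import STRATA, Gender, StratumKey, stratum_from_labels

__all__ = [
    "RunConfig",
    "ValidationReport",
    "validate_inputs",
    "read_life_table",
    "read_population",
    "read_survival_curves",
    "read_prevalence",
    "read_incidence",
    "build_context",
]

REQUIRED_COLUMNS = {
    "life_table": ["age", "gender", "race", "mu_h"],
    "population": ["age", "gender", "race", "N"],
    "reference_distribution": ["age", "gender", "race", "proportion"],
    "mm_survival": ["time_years", "surviving_fraction", "gender", "race"],
    "prevalence": ["age_lo", "age_hi", "gender", "race", "y", "n"],
    "incidence": ["age_lo", "age_hi", "gender", "race", "incidence_per_100k"],
}


@dataclass
class RunConfig:
    """One calibration run: input paths, priors, sampler settings,
    model-variant flags, grid, output directory."""

    life_table: Path
    population: Path
    reference_distribution: Path
    mm_survival: Path
    prevalence: Path
    incidence: Path
    out_dir: Path
    prior_bounds: dict = field(default_factory=lambda: dict(DEFAULT_PRIOR_BOUNDS))
    n_iterations: int = 1_000_000
    burn_in: int = 500_000
    thin: int = 50
    n_chains: int = 5
    seed: int = 0
    quad_mm_age: bool = True
    mgus_mortality_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_MGUS_MULTIPLIERS))
    age_start: int = 0
    age_end: int = 99
    age_step: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        paths = {k: base / raw[k] for k in ("life_table", "population",
                                            "reference_distribution", "mm_survival",
                                            "prevalence", "incidence", "out_dir")}
        opts = {k: v for k, v in raw.items() if k not in paths}
        if "prior_bounds" in opts:
            opts["prior_bounds"] = {k: tuple(v) for k, v in opts["prior_bounds"].items()}
        return cls(**paths, **opts)

    def grid(self) -> AgeGrid:
        return AgeGrid(self.age_start, self.age_end, self.age_step)

    def input_paths(self) -> dict[str, Path]:
        return {k: getattr(self, k) for k in ("life_table", "population",
                                              "reference_distribution", "mm_survival",
                                              "prevalence", "incidence")}

    def checksums(self) -> dict[str, str]:
        return {k: hashlib.sha256(p.read_bytes()).hexdigest()[:16]
                for k, p in self.input_paths().items()}


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "all inputs valid"


def _check_frame(name: str, df: pd.DataFrame, report: ValidationReport) -> bool:
    missing = [c for c in REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        report.errors.append(f"{name}: missing columns {missing}")
        return False
    if "gender" in df.columns:
        bad = set(df.gender.unique()) - {g.value for g in Gender}
        if bad:
            report.errors.append(f"{name}: unknown gender labels {sorted(bad)}")
            return False
    if "race" in df.columns:
        bad = set(df.race.unique()) - {"NHW", "NHB"}
        if bad:
            report.errors.append(f"{name}: unknown race labels {sorted(bad)}")
            return False
    return True


def validate_inputs(paths: dict[str, str | Path]) -> ValidationReport:
    """Schema and consistency checks with row-level diagnostics."""
    report = ValidationReport()
    frames = {}
    for name in REQUIRED_COLUMNS:
        p = Path(paths[name])
        if not p.exists():
            report.errors.append(f"{name}: file not found at {p}")
            continue
        df = pd.read_csv(p)
        if _check_frame(name, df, report):
            frames[name] = df

    if "prevalence" in frames:
        df = frames["prevalence"]
        for idx, row in df.iterrows():
            if row.y > row.n:
                report.errors.append(f"prevalence row {idx}: y={row.y} exceeds n={row.n}")
            if row.age_lo > row.age_hi:
                report.errors.append(f"prevalence row {idx}: age_lo > age_hi")
        _check_bin_overlap("prevalence", df, report)
    if "incidence" in frames:
        df = frames["incidence"]
        for idx, row in df.iterrows():
            if row.incidence_per_100k <= 0:
                report.warnings.append(
                    f"incidence row {idx}: non-positive rate, will be excluded")
            if row.age_lo > row.age_hi:
                report.errors.append(f"incidence row {idx}: age_lo > age_hi")
        _check_bin_overlap("incidence", df, report)
    if "life_table" in frames and (frames["life_table"].mu_h < 0).any():
        report.errors.append("life_table: negative mortality rates")
    if "mm_survival" in frames:
        df = frames["mm_survival"]
        if ((df.surviving_fraction <= 0) | (df.surviving_fraction > 1)).any():
            report.errors.append("mm_survival: surviving_fraction outside (0, 1]")
    return report


def _check_bin_overlap(name: str, df: pd.DataFrame, report: ValidationReport) -> None:
    for (g, r), sub in df.groupby(["gender", "race"]):
        sub = sub.sort_values("age_lo")
        prev_hi = -1
        for idx, row in sub.iterrows():
            if row.age_lo <= prev_hi:
                report.errors.append(
                    f"{name} row {idx} ({g}/{r}): bin [{row.age_lo}, {row.age_hi}] "
                    f"overlaps the previous bin")
            prev_hi = max(prev_hi, row.age_hi)


# -- readers ---------------------------------------------------------------


def read_life_table(path: str | Path) -> dict[tuple[int, StratumKey], float]:
    df = pd.read_csv(path)
    return {(int(r.age), stratum_from_labels(r.gender, r.race)): float(r.mu_h)
            for r in df.itertuples()}


def read_population(path: str | Path, reference_path: str | Path) -> PopulationTable:
    """Population counts; open-ended "<age>+" rows are disaggregated
    with the reference age distribution."""
    df = pd.read_csv(path, dtype={"age": str})
    ref = pd.read_csv(reference_path)
    counts: dict[tuple[int, StratumKey], float] = {}
    for r in df.itertuples():
        st = stratum_from_labels(r.gender, r.race)
        age = str(r.age).strip()
        if age.endswith("+"):
            rsub = ref[(ref.gender == r.gender) & (ref.race == r.race)]
            if rsub.empty:
                raise ValueError(f"no reference distribution for {r.gender}/{r.race}")
            dist = {int(a): float(p) for a, p in zip(rsub.age, rsub.proportion)}
            for a, n in disaggregate_open_age_bin(float(r.N), dist).items():
                counts[(a, st)] = counts.get((a, st), 0.0) + n
        else:
            counts[(int(age), st)] = float(r.N)
    return PopulationTable(counts)


def read_survival_curves(path: str | Path) -> dict[StratumKey, SurvivalCurve]:
    df = pd.read_csv(path)
    out = {}
    for (g, r), sub in df.groupby(["gender", "race"]):
        st = stratum_from_labels(g, r)
        sub = sub.sort_values("time_years")
        out[st] = SurvivalCurve(times=sub.time_years.to_numpy(),
                                fractions=sub.surviving_fraction.to_numpy(),
                                stratum=st)
    return out


def read_prevalence(path: str | Path) -> list[PrevalenceObservation]:
    df = pd.read_csv(path)
    return [PrevalenceObservation(a_lo=int(r.age_lo), a_hi=int(r.age_hi),
                                  stratum=stratum_from_labels(r.gender, r.race),
                                  y=int(r.y), n=int(r.n))
            for r in df.itertuples()]


def read_incidence(path: str | Path) -> tuple[list[IncidenceObservation], int]:
    """Rates are converted from per-100,000 person-years to per
    person-year; non-positive rows are dropped (count returned)."""
    df = pd.read_csv(path)
    kept = df[df.incidence_per_100k > 0]
    n_excluded = len(df) - len(kept)
    obs = [IncidenceObservation(a_lo=int(r.age_lo), a_hi=int(r.age_hi),
                                stratum=stratum_from_labels(r.gender, r.race),
                                x=float(r.incidence_per_100k) / PER_100K)
           for r in kept.itertuples()]
    return obs, n_excluded


def build_context(config: RunConfig) -> tuple[ModelContext, dict]:
    """Assemble the fit-ready ModelContext from a run config.

    Returns (context, metadata) where metadata records the fitted MM
    mortality rates, the incidence-row exclusions, the unit conversion
    and input checksums.
    """
    report = validate_inputs(config.input_paths())
    if not report.ok:
        raise ValueError(f"invalid inputs:\n{report}")

    mu_h = read_life_table(config.life_table)
    population = read_population(config.population, config.reference_distribution)
    curves = read_survival_curves(config.mm_survival)
    mm_rates = {st: fit_exponential_survival(c) for st, c in curves.items()}
    mult = {Gender(k): float(v) for k, v in config.mgus_mortality_multipliers.items()}
    mortality = MortalitySchedule(mu_h=mu_h, mgus_multiplier=mult, mu_mm=mm_rates)

    prev_obs = read_prevalence(config.prevalence)
    inc_obs, n_excluded = read_incidence(config.incidence)
    prior = PriorSpec(bounds={k: tuple(v) for k, v in config.prior_bounds.items()})
    context = ModelContext(mortality=mortality, population=population,
                           grid=config.grid(), prev_obs=prev_obs, inc_obs=inc_obs,
                           prior=prior, quad_mm_age=config.quad_mm_age)
    meta = {
        "mm_mortality_rates": {st.label(): mm_rates[st] for st in STRATA},
        "incidence_rows_excluded": n_excluded,
        "incidence_unit_conversion": f"per 100,000 -> per person-year (/{PER_100K:.0f})",
        "input_checksums": config.checksums(),
        "quad_mm_age": config.quad_mm_age,
        "mgus_mortality_multipliers": {k: float(v) for k, v
                                       in config.mgus_mortality_multipliers.items()},
    }
    return context, meta
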