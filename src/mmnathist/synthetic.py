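"""Synthetic input datasets with known ground truth.

Generates all five input tables the calibration pipeline consumes —
age-binned MGUS prevalence counts, age-binned MM incidence rates, a
life table, a population table (with an open 85+ row), and MM survival
curves — from a known parameter vector, so parameter recovery and
every downstream stage can be exercised end to end without external
data.

The default ("paper-like") truth is anchored to the published
posterior medians: an MGUS onset rate of 0.0012/yr at age 60 rising to
0.0034/yr at age 80, a female MGUS multiplier of 0.59 and an NHB
multiplier of 2.0, and an MM progression rate peaking at age 71 with
multipliers 1.1 (female) and 1.2 (NHB). These are targets distilled
from a fitted model, not the ground truth of the real surveys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AgeGrid, MortalitySchedule, integrate_cohort, mm_rate, state_prevalence
from .demography import PopulationTable, SurvivalCurve, disaggregate_open_age_bin
from .likelihood import PER_100K, IncidenceObservation, PrevalenceObservation
from .params import ParameterVector
from .strata import STRATA, Gender, StratumKey

__all__ = [
    "SyntheticDesign",
    "paper_like_truth",
    "generate_truth_curves",
    "sample_observations",
    "generate_support_tables",
    "generate_dataset",
    "write_dataset",
]

#: NHANES 1999-2004 MGUS-tested sample sizes by stratum
#: (NHW men, NHW women, NHB men, NHB women).
NHANES_SAMPLE_SIZES = (1735, 1703, 454, 463)

PREVALENCE_BINS = tuple((a, a + 4) for a in range(50, 85, 5)) + ((85, 99),)
INCIDENCE_BINS = tuple((a, a + 4) for a in range(30, 85, 5)) + ((85, 99),)
OPEN_BIN_START = 85
MAX_TABLE_AGE = 99


def paper_like_truth() -> ParameterVector:
    """Generating parameters anchored to the published estimates.

    gamma/slope for MGUS reproduce rates 0.0012/yr at 60 and 0.0034/yr
    at 80; the MM quadratic peaks at age 71 (vertex -b/(2c) with
    b = 0.142, c = -0.001) at about 0.015/yr.
    """
    return ParameterVector(
        gamma_mgus=-9.85,
        beta_mgus_a=0.052,
        beta_mgus_s=float(np.log(0.59)),
        beta_mgus_r=float(np.log(2.0)),
        gamma_mm=-9.24,
        beta_mm_a=0.142,
        beta_mm_a2=-0.001,
        beta_mm_s=float(np.log(1.1)),
        beta_mm_r=float(np.log(1.2)),
        tau2=0.01,
    )


@dataclass
class SyntheticDesign:
    """Study design for one synthetic dataset.

    Defaults emulate the real inputs: 5-year prevalence bins from 50
    with an open 85+ bin and NHANES-scale tested counts allocated
    across bins proportional to population; 5-year incidence bins
    30-84 plus 85+; Gompertz background mortality mu_H = b exp(c a)
    with stratum-specific level; exponential MM survival.
    """

    truth: ParameterVector = field(default_factory=paper_like_truth)
    prevalence_bins: tuple = PREVALENCE_BINS
    incidence_bins: tuple = INCIDENCE_BINS
    tested_counts: dict = field(
        default_factory=lambda: dict(zip(STRATA, NHANES_SAMPLE_SIZES)))
    #: per-stratum Gompertz level b (per year at age 0); slope c shared
    gompertz_b: dict = field(default_factory=lambda: dict(
        zip(STRATA, (1.0e-4, 0.7e-4, 1.4e-4, 1.0e-4))))
    gompertz_c: float = 0.085
    #: per-stratum MM all-cause mortality rate (per year)
    mm_rates: dict = field(default_factory=lambda: dict(
        zip(STRATA, (0.20, 0.18, 0.22, 0.20))))
    #: per-stratum population level at age 0; shape shared
    population_base: dict = field(default_factory=lambda: dict(
        zip(STRATA, (1.2e6, 1.2e6, 2.0e5, 2.0e5))))
    population_shape: float = 3.5e-4  # N(a) ∝ exp(-shape * a^2)
    survival_times: tuple = tuple(range(1, 11))
    grid: AgeGrid = field(default_factory=AgeGrid)
    seed: int = 0

    def __post_init__(self) -> None:
        for bins in (self.prevalence_bins, self.incidence_bins):
            prev_hi = -1
            for a_lo, a_hi in bins:
                if a_lo > a_hi or a_lo <= prev_hi:
                    raise ValueError("bins must be ordered and non-overlapping")
                prev_hi = a_hi
        if any(n <= 0 for n in self.tested_counts.values()):
            raise ValueError("tested counts must be positive")

    # -- deterministic support tables -------------------------------------

    def population_counts(self) -> dict[tuple[int, StratumKey], float]:
        ages = np.arange(0, MAX_TABLE_AGE + 1)
        shape = np.exp(-self.population_shape * ages.astype(float) ** 2)
        return {(int(a), st): float(self.population_base[st] * shape[a])
                for st in STRATA for a in ages}

    def population_table(self) -> PopulationTable:
        return PopulationTable(self.population_counts())

    def mortality_schedule(self, mgus_multipliers: dict | None = None) -> MortalitySchedule:
        mu_h = {(a, st): float(self.gompertz_b[st] * np.exp(self.gompertz_c * a))
                for st in STRATA for a in range(MAX_TABLE_AGE + 1)}
        mult = ({Gender.male: 1.25, Gender.female: 1.11}
                if mgus_multipliers is None else mgus_multipliers)
        return MortalitySchedule(mu_h=mu_h, mgus_multiplier=mult,
                                 mu_mm=dict(self.mm_rates))

    def allocate_tested_counts(self) -> dict[tuple[tuple[int, int], StratumKey], int]:
        """Allocate each stratum's total tested n across prevalence bins
        proportional to bin population (largest-remainder rounding)."""
        pop = self.population_table()
        out: dict[tuple[tuple[int, int], StratumKey], int] = {}
        for st in STRATA:
            w = np.array([sum(pop.count(a, st) for a in range(lo, hi + 1))
                          for lo, hi in self.prevalence_bins])
            total = self.tested_counts[st]
            exact = total * w / w.sum()
            base = np.floor(exact).astype(int)
            rem = total - base.sum()
            order = np.argsort(-(exact - base))
            base[order[:rem]] += 1
            for b, n in zip(self.prevalence_bins, base):
                out[(b, st)] = int(n)
        return out


def generate_truth_curves(design: SyntheticDesign) -> pd.DataFrame:
    """Exact model output at the generating parameters.

    Columns: age, gender, race, p_mgus (alive-conditioned prevalence),
    i_mm (incidence per person-year). Deterministic.
    """
    mortality = design.mortality_schedule()
    rows = []
    for st in STRATA:
        traj = integrate_cohort(design.truth, mortality, design.grid, st)
        for a in range(int(design.grid.age_start), int(design.grid.age_end) + 1):
            _, p_mgus, _ = state_prevalence(traj, float(a))
            rows.append({
                "age": a, "gender": st.gender.value, "race": st.race.value,
                "p_mgus": p_mgus,
                "i_mm": mm_rate(design.truth, float(a), st) * p_mgus,
            })
    return pd.DataFrame(rows)


def _bin_means(curves: pd.DataFrame, col: str, bins, design: SyntheticDesign):
    pop = design.population_table()
    out = {}
    for st in STRATA:
        sub = curves[(curves.gender == st.gender.value)
                     & (curves.race == st.race.value)].set_index("age")[col]
        for lo, hi in bins:
            ages = range(lo, hi + 1)
            w = np.array([pop.count(a, st) for a in ages])
            v = np.array([sub.loc[a] for a in ages])
            out[((lo, hi), st)] = float((w * v).sum() / w.sum())
    return out


def sample_observations(curves: pd.DataFrame, design: SyntheticDesign,
                        seed: int | None = None,
                        ) -> tuple[list[PrevalenceObservation], list[IncidenceObservation]]:
    """Draw one observation set around the truth curves.

    Prevalence: y ~ Binomial(n_bin, pbar_bin). Incidence:
    x = exp(Normal(log ibar_bin, tau^2)). Reproducible for a fixed
    seed (defaults to the design's master seed).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    pbar = _bin_means(curves, "p_mgus", design.prevalence_bins, design)
    ibar = _bin_means(curves, "i_mm", design.incidence_bins, design)
    tested = design.allocate_tested_counts()

    prev = []
    for st in STRATA:
        for b in design.prevalence_bins:
            n = tested[(b, st)]
            y = int(rng.binomial(n, pbar[(b, st)]))
            prev.append(PrevalenceObservation(a_lo=b[0], a_hi=b[1], stratum=st, y=y, n=n))
    inc = []
    sd = float(np.sqrt(design.truth.tau2))
    for st in STRATA:
        for b in design.incidence_bins:
            x = float(np.exp(rng.normal(np.log(ibar[(b, st)]), sd))) if sd > 0 \
                else ibar[(b, st)]
            inc.append(IncidenceObservation(a_lo=b[0], a_hi=b[1], stratum=st, x=x))
    return prev, inc


def generate_support_tables(design: SyntheticDesign) -> dict[str, pd.DataFrame]:
    """Life table, population (with 85+ aggregate row), 85-99 reference
    distribution, and MM survival curves, as tidy frames."""
    life_rows = []
    for st in STRATA:
        for a in range(MAX_TABLE_AGE + 1):
            life_rows.append({"age": a, "gender": st.gender.value,
                              "race": st.race.value,
                              "mu_h": design.gompertz_b[st] * np.exp(design.gompertz_c * a)})

    counts = design.population_counts()
    pop_rows = []
    ref_rows = []
    for st in STRATA:
        for a in range(OPEN_BIN_START):
            pop_rows.append({"age": str(a), "gender": st.gender.value,
                             "race": st.race.value, "N": counts[(a, st)]})
        open_ages = range(OPEN_BIN_START, MAX_TABLE_AGE + 1)
        agg = sum(counts[(a, st)] for a in open_ages)
        pop_rows.append({"age": f"{OPEN_BIN_START}+", "gender": st.gender.value,
                         "race": st.race.value, "N": agg})
        for a in open_ages:
            ref_rows.append({"age": a, "gender": st.gender.value,
                             "race": st.race.value,
                             "proportion": counts[(a, st)] / agg})

    surv_rows = []
    for st in STRATA:
        mu = design.mm_rates[st]
        for t in design.survival_times:
            surv_rows.append({"time_years": float(t),
                              "surviving_fraction": float(np.exp(-mu * t)),
                              "gender": st.gender.value, "race": st.race.value})

    return {
        "life_table": pd.DataFrame(life_rows),
        "population": pd.DataFrame(pop_rows),
        "reference_distribution": pd.DataFrame(ref_rows),
        "mm_survival": pd.DataFrame(surv_rows),
    }


def generate_dataset(design: SyntheticDesign, seed: int | None = None) -> dict:
    """One complete synthetic study: support tables, truth curves, and a
    sampled observation set (as tidy frames, ready for writing)."""
    curves = generate_truth_curves(design)
    prev, inc = sample_observations(curves, design, seed=seed)
    tables = generate_support_tables(design)
    tables["prevalence"] = pd.DataFrame(
        [{"age_lo": o.a_lo, "age_hi": o.a_hi, "gender": o.stratum.gender.value,
          "race": o.stratum.race.value, "y": o.y, "n": o.n} for o in prev])
    tables["incidence"] = pd.DataFrame(
        [{"age_lo": o.a_lo, "age_hi": o.a_hi, "gender": o.stratum.gender.value,
          "race": o.stratum.race.value, "incidence_per_100k": o.x * PER_100K}
         for o in inc])
    tables["truth_curves"] = curves
    return tables


def write_dataset(design: SyntheticDesign, out_dir: str | Path,
                  seed: int | None = None) -> Path:
    """Write the five input CSVs plus truth.json into out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = generate_dataset(design, seed=seed)
    for name in ("life_table", "population", "reference_distribution",
                 "mm_survival", "prevalence", "incidence"):
        tables[name].to_csv(out / f"{name}.csv", index=False)
    truth = {"parameters": design.truth.to_dict(),
             "mm_rates": {st.label(): design.mm_rates[st] for st in STRATA},
             "seed": design.seed if seed is None else seed}
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return out


def reassemble_population(design: SyntheticDesign) -> PopulationTable:
    """Round-trip helper: disaggregate the emitted 85+ rows with the
    emitted reference distribution (what the reader does)."""
    tables = generate_support_tables(design)
    pop = tables["population"]
    ref = tables["reference_distribution"]
    counts: dict[tuple[int, StratumKey], float] = {}
    for st in STRATA:
        sub = pop[(pop.gender == st.gender.value) & (pop.race == st.race.value)]
        for _, row in sub.iterrows():
            if str(row["age"]).endswith("+"):
                rsub = ref[(ref.gender == st.gender.value) & (ref.race == st.race.value)]
                dist = {int(a): float(p) for a, p in zip(rsub.age, rsub.proportion)}
                for a, n in disaggregate_open_age_bin(float(row["N"]), dist).items():
                    counts[(a, st)] = n
            else:
                counts[(int(row["age"]), st)] = float(row["N"])
    return PopulationTable(counts)
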