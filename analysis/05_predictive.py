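"""Posterior-predictive check of the fitted model.

Builds 50% and 95% posterior prediction intervals for every
observation bin (binomial noise for prevalence, lognormal for
incidence) and reports how many observed bins the 95% band covers.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mmnathist.inference import ChainSet, posterior_predictive
from mmnathist.io import RunConfig, build_context

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = RunConfig.from_yaml(RESULTS / "config.yaml")
    context, _ = build_context(config)
    chains = ChainSet.from_dataframe(pd.read_csv(RESULTS / "fit" / "posterior.csv"))
    bands = posterior_predictive(chains, context, seed=config.seed)

    rows = []
    for o, q in zip(context.prev_obs, bands.prevalence):
        rows.append({"table": "prevalence", "age_lo": o.a_lo, "age_hi": o.a_hi,
                     "gender": o.stratum.gender.value, "race": o.stratum.race.value,
                     "observed": o.y / o.n, "q2.5": q[0], "q25": q[1], "q50": q[2],
                     "q75": q[3], "q97.5": q[4]})
    for o, q in zip(context.inc_obs, bands.incidence):
        rows.append({"table": "incidence", "age_lo": o.a_lo, "age_hi": o.a_hi,
                     "gender": o.stratum.gender.value, "race": o.stratum.race.value,
                     "observed": o.x, "q2.5": q[0], "q25": q[1], "q50": q[2],
                     "q75": q[3], "q97.5": q[4]})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "predictive_bands.csv", index=False)

    obs_prev = np.array([o.y / o.n for o in context.prev_obs])
    obs_inc = np.array([o.x for o in context.inc_obs])
    cov = bands.coverage_95(obs_prev, obs_inc)
    n_bins = len(rows)
    print(f"{int(round(cov * n_bins))}/{n_bins} observed bins fall inside the "
          f"95% posterior prediction interval ({100 * cov:.1f}%)")


if __name__ == "__main__":
    main()
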