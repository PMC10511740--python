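"""Convergence diagnostics and model comparison.

Computes the Gelman-Rubin statistic per parameter for the fitted
chains, the DIC of the fitted (quadratic-age) model, and refits the
variant without the quadratic MM age term to compare DICs — the
model-selection question of whether MM progression risk declines at
high ages.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mmnathist.inference import ChainSet, McmcSettings, dic, gelman_rubin, run_mcmc
from mmnathist.io import RunConfig, build_context

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = RunConfig.from_yaml(RESULTS / "config.yaml")
    context, _ = build_context(config)
    chains = ChainSet.from_dataframe(pd.read_csv(RESULTS / "fit" / "posterior.csv"))

    rhat = gelman_rubin(chains)
    df = pd.DataFrame({"parameter": chains.param_names,
                       "gelman_rubin": np.round(rhat, 4)})
    df.to_csv(RESULTS / "diagnostics.csv", index=False)
    print(df.to_string(index=False))
    print(f"max Gelman-Rubin: {rhat.max():.4f} "
          f"({'converged' if rhat.max() < 1.1 else 'NOT converged'} at the 1.1 threshold)")

    dic_quad = dic(chains, context.log_likelihood, max_draws=2000)

    config_lin = RunConfig.from_yaml(RESULTS / "config.yaml")
    config_lin.quad_mm_age = False
    context_lin, _ = build_context(config_lin)
    settings = McmcSettings(n_iterations=config.n_iterations, burn_in=config.burn_in,
                            thin=config.thin, n_chains=config.n_chains,
                            seed=config.seed)
    chains_lin = run_mcmc(context_lin, settings)
    dic_lin = dic(chains_lin, context_lin.log_likelihood, max_draws=2000)

    cmp = {"dic_quadratic": dic_quad.dic, "p_d_quadratic": dic_quad.p_d,
           "dic_linear": dic_lin.dic, "p_d_linear": dic_lin.p_d,
           "quadratic_preferred": bool(dic_quad.dic < dic_lin.dic)}
    (RESULTS / "dic_comparison.json").write_text(json.dumps(cmp, indent=2))
    print(f"DIC quadratic: {dic_quad.dic:.1f} (p_D {dic_quad.p_d:.1f}); "
          f"linear: {dic_lin.dic:.1f} (p_D {dic_lin.p_d:.1f})")
    print("quadratic age term preferred" if cmp["quadratic_preferred"]
          else "linear model preferred")


if __name__ == "__main__":
    main()
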