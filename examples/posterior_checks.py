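"""Posterior predictive checks and the predicted abundance series.

Fits the model to a simulated dataset, then (a) draws 1000 replicate
datasets from the posterior predictive distribution and compares their
kernel densities and mean/SD statistics with the observed channels, and
(b) prints the predicted total-abundance trajectory with 50%/95% bands.
Figures are written next to this script.  Runtime: about a minute.
"""

import warnings
from pathlib import Path

from deerssm import (
    FOREST_AREA_KM2,
    MCMCSettings,
    ppc_density_overlay,
    predicted_abundance_series,
    run_mcmc,
    scenario_from_study_defaults,
    simulate_dataset,
    simulate_replicates,
)

out_dir = Path(__file__).resolve().parent

scenario = scenario_from_study_defaults()
data, truth = simulate_dataset(scenario, seed=7)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    draws = run_mcmc(data, settings=MCMCSettings.reduced(), seed=1)
    ppc = simulate_replicates(draws, data, n_rep=1000, seed=2)

for channel in ("C_A", "C_B", "C_E", "B"):
    fig, coverage = ppc_density_overlay(
        ppc, channel, path=out_dir / f"ppc_density_{channel}.png"
    )
    enclosed = ppc.stat_cloud_encloses_observed(channel)
    print(f"{channel}: density envelope coverage {coverage:.2f}; observed "
          f"mean/SD inside replicate cloud: {enclosed}")

pred = predicted_abundance_series(draws, seed=3, forest_area_km2=FOREST_AREA_KM2)
peak = pred.loc[pred["mean"].idxmax()]
print()
print(pred.head(8).round(1))
print()
print(f"Peak predicted abundance: {peak['mean']:.0f} animals at period "
      f"t={int(peak['t'])} ({peak['mean']/FOREST_AREA_KM2:.1f} per km^2); "
      f"true peak {truth.N.max():.0f}.")
print("Coverage near 1 and an enclosed mean/SD point mean the fitted model "
      "reproduces the distribution of its own data - the graphical check "
      "used to validate the model.")
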