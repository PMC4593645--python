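"""Fit and evaluate a presence-only habitat suitability model.

Simulates an environmental stack (one smooth field drives habitat
choice, two are decoys), draws presence points proportional to
exp(2 x driver), and runs the replicate evaluation: 50 random 70/30
presence splits, test AUC against the background, percent and
permutation contributions per variable, and jackknife gains.
"""

import numpy as np

from foragescape.grids import GridSpec, Raster
from foragescape.habitat import evaluate
from foragescape.simulate import simulate_presences, simulate_raster

grid = GridSpec(xll=-26.0, yll=12.0, ncols=50, nrows=50, cell_deg=0.12)
sst = simulate_raster(grid, "noise", {"sigma_cells": 2.0, "gaussianize": True},
                      seed=11, name="SST")
chl = simulate_raster(grid, "noise", {"sigma_cells": 2.0}, seed=12, name="CHL")
wspd = simulate_raster(grid, "noise", {"sigma_cells": 2.0}, seed=13, name="WSPD")

suitability = Raster("truth", grid, np.exp(2.0 * sst.values))
presences, _ = simulate_presences(suitability, 400, seed=1)

ev = evaluate(presences, [sst, chl, wspd], replicates=50, seed=2)
print(f"mean test AUC over {ev.n_replicates} replicates: "
      f"{ev.mean_auc:.3f} ({ev.category})")
print("\nvariable        percent   permutation   jackknife-alone gain")
for v in ("SST", "CHL", "WSPD"):
    print(f"{v:<14}{ev.percent_contribution[v]:>8.1f}%"
          f"{ev.permutation_contribution[v]:>12.1f}%"
          f"{ev.jackknife[v]['alone']:>16.3f}")
print("\nSST was the only true driver: it should dominate both contribution "
      "schemes, and AUC near 0.92 matches the theoretical ceiling "
      "Phi(sqrt(2)) for this generating model.")
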