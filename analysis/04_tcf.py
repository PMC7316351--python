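#!/usr/bin/env python
"""Triple-correlation analysis of the demo scene: f(r1, r2, Δθ), the
θ-averaged f(r1, r2, r3), and the conditional density C3.

Reads results/demo/scene.csv; writes tcf.h5 and tcf_angular.csv and prints
where the correlation peaks relative to the planted geometry.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tricolo.correlate import (angular_average, compute_conditional_density,
                               compute_tcf, select_roi)
from tricolo.io import write_tcf_grid

OUT = Path("results/demo")

table = pd.read_csv(OUT / "scene.csv")
params = json.loads((OUT / "scene.json").read_text())
roi = select_roi(table[table.x_nm.between(0, 6000) & table.y_nm.between(0, 6000)],
                 center=(3000.0, 3000.0), side=6000.0)
print("mean densities (/µm²):",
      {c: round(d * 1e6, 1) for c, d in roi.mean_densities.items()})

edges = np.arange(0.0, 521.0, 40.0)
grid = compute_tcf(roi, edges, edges, ntheta=12, boundary_mode="analytic")
angular_average(grid, convention="minus")
compute_conditional_density(grid, roi)
write_tcf_grid(grid, OUT / "tcf.h5", OUT / "tcf_angular.csv")

f = np.nan_to_num(grid.f_values, nan=-np.inf)
a, b, d = np.unravel_index(np.argmax(f), f.shape)
print(f"f peak: r1 in [{edges[a]:.0f},{edges[a+1]:.0f}) nm, "
      f"r2 in [{edges[b]:.0f},{edges[b+1]:.0f}) nm, "
      f"dtheta = {np.degrees(grid.dtheta_centers[d]):.0f} deg "
      f"(f = {f[a, b, d]:.1f})")
print(f"planted: r1 = {params['r1_nm']:.0f} nm, r2 = {params['r2_nm']:.0f} nm, "
      f"dtheta = {np.degrees(params['dtheta_rad']):.0f} deg")
c3 = np.nan_to_num(grid.c3_values, nan=-np.inf)
a2, b2, d2 = np.unravel_index(np.argmax(c3), c3.shape)
print(f"C3 peak at the same geometry: {(a2, b2, d2) == (a, b, d)}; "
      f"local density {c3[a2, b2, d2] * 1e6:.0f}/µm² vs ROI mean "
      f"{roi.mean_densities[3] * 1e6:.0f}/µm²")
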