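#!/usr/bin/env python
"""Condition-level endpoint: NT vs PDS fold change with propagated SEM and
Welch's t-test, from the per-nucleus densities of 05_associate.py.

Writes results/cohort/fold_change.csv.
"""

from pathlib import Path

import pandas as pd

from tricolo.quantify import summarize_cohort

OUT = Path("results/cohort")

per = pd.read_csv(OUT / "per_nucleus.csv")
summary = summarize_cohort(per, variant="welch")
summary.to_csv(OUT / "fold_change.csv", index=False)
for r in summary.itertuples(index=False):
    print(f"{r.cell_line}: NT {r.mean_NT:.3f} ± {r.sd_NT:.3f}/µm² (n={r.n_NT}), "
          f"PDS {r.mean_PDS:.3f} ± {r.sd_PDS:.3f}/µm² (n={r.n_PDS})")
    print(f"  fold change {r.ratio:.2f} ± {r.propagated_sem:.2f} "
          f"(propagated SEM), Welch p = {r.p_value:.2e}")
print(f"-> {OUT/'fold_change.csv'}")
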