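#!/usr/bin/env python
"""Microcluster-foci colocalization with the 5 px shift chance control.

Contrasts a correlated channel pair (half the clusters planted on foci,
the TCR-like case) with an independently placed pair (the ICAM1-like
case): shifting the foci mask should collapse the former to chance and
leave the latter unchanged.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

import synfoci as sf
from synfoci.simulate import cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260918
N_CELLS = 20

rows = []
for label, f in (("tcr_like", 0.5), ("icam1_like", None)):
    params = sf.SynapseParams(seed=SEED + (0 if f else 7), coloc_fraction=f)
    for i, (actin, clusters, cell, _) in enumerate(cohort(params, N_CELLS)):
        pair = sf.coloc_with_chance(clusters, actin, cell)
        rows.append(
            {
                "condition": label,
                "cell_id": i + 1,
                "fraction": pair.observed.fraction,
                "fraction_shifted": pair.chance.fraction,
                "fraction_objects": pair.observed_objects.fraction,
                "n_subject_px": int(pair.subject_foci.mask.sum()),
                "n_overlap_px": int((pair.subject_foci.mask & pair.reference_foci.mask).sum()),
            }
        )

table = pd.DataFrame(rows)
table.to_csv(ROOT / "results" / "coloc.csv", index=False)

for label in ("tcr_like", "icam1_like"):
    sub = table[table.condition == label]
    p = sf.format_p(sf.wilcoxon_signed_rank(sub.fraction, sub.fraction_shifted).p_value)
    m, sem = sf.mean_sem(sub.fraction)
    mc, _ = sf.mean_sem(sub.fraction_shifted)
    print(f"{label}: fraction colocalized {m:.3f} ± {sem:.3f}, "
          f"shift control {mc:.3f}, paired Wilcoxon p = {p}")
print("per-cell table -> results/coloc.csv")
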