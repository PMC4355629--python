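#!/usr/bin/env python
"""Detect F-actin foci with the median rank-filter pipeline.

Reproduces the two validation figures of the method on synthetic data: the
25/50/75 percentile sweep (lower percentiles under-subtract and inflate the
foci mask) and the foci-pixel intensity histogram (foci pixels are a small,
high-intensity subset of the synapse).  Emits per-focus and per-cell tables.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import synfoci as sf
from synfoci.dynamics import average_histograms
from synfoci.simulate import cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260918
N_CELLS = 13

params = sf.SynapseParams(seed=SEED)
foci_rows, cell_rows, hists, sweep_rows = [], [], [], []
recovered = planted = 0
for i, (actin, _, cell, truth) in enumerate(cohort(params, N_CELLS)):
    cell_id = i + 1
    foci, hp = sf.detect_foci_pipeline(actin, cell)
    metrics = sf.foci_metrics_per_cell(foci, hp, cell)
    m, nd, nt = sf.match_centroids(foci.centroids(), truth.foci_centers, 2.0)
    recovered += m
    planted += nt
    table = foci.foci.copy()
    table.insert(0, "cell_id", cell_id)
    foci_rows.append(table)
    cell_rows.append(
        {
            "cell_id": cell_id,
            "area_px": cell.area_px,
            "foci_count": metrics.foci_count,
            "total_foci_intensity": metrics.total_foci_intensity,
            "total_cell_intensity": metrics.total_cell_intensity,
            "foci_pixel_fraction": metrics.foci_pixel_fraction,
        }
    )
    hists.append(sf.foci_pixel_histogram(actin, foci, cell))
    sweep = sf.percentile_sweep(actin, cell)
    sweep_rows.append(
        {"cell_id": cell_id, **{f"area_p{int(p)}": int(s.mask.sum()) for p, s in sweep.items()}}
    )

pd.concat(foci_rows, ignore_index=True).to_csv(ROOT / "results" / "foci.csv", index=False)
cells = pd.DataFrame(cell_rows)
cells.to_csv(ROOT / "results" / "cells.csv", index=False)
average_histograms(hists).to_csv(ROOT / "results" / "foci_histogram.csv", index=False)
sweep_df = pd.DataFrame(sweep_rows)
sweep_df.to_csv(ROOT / "results" / "percentile_sweep.csv", index=False)

print(f"detected {cells.foci_count.sum()} foci across {N_CELLS} cells "
      f"(recall vs planted: {recovered / planted:.2f})")
print(f"foci pixels occupy {100 * cells.foci_pixel_fraction.mean():.1f}% of the synapse on average "
      f"(max {100 * cells.foci_pixel_fraction.max():.1f}%) — the <10% regime")
print("percentile sweep mean areas (px): "
      + ", ".join(f"p{p}={sweep_df[f'area_p{p}'].mean():.0f}" for p in (25, 50, 75)))
print("tables -> results/foci.csv, cells.csv, foci_histogram.csv, percentile_sweep.csv")
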