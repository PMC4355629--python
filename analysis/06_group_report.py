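#!/usr/bin/env python
"""Two-condition group comparison: control vs foci-deficient synapses.

Simulates the canonical contrast — cells with a normal complement of foci
against cells with almost none (the WASP-loss phenotype) but identical
lamellar F-actin — and compares per-cell total foci intensity, normalized
to the control-group mean, with the Mann-Whitney test.  Total raw synaptic
F-actin is reported alongside: because foci carry only a few percent of
the synaptic signal, their loss barely moves the whole-synapse intensity.
"""

from pathlib import Path

import pandas as pd

import synfoci as sf
from synfoci.simulate import cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260918
N_CELLS = 25

rows = []
for condition, n_foci in (("control", 20), ("foci_deficient", 2)):
    params = sf.SynapseParams(seed=SEED + (0 if n_foci == 20 else 1), n_foci=n_foci)
    for i, (actin, _, cell, _) in enumerate(cohort(params, N_CELLS)):
        foci, hp = sf.detect_foci_pipeline(actin, cell)
        metrics = sf.foci_metrics_per_cell(foci, hp, cell)
        rows.append(
            {
                "condition": condition,
                "cell_id": i + 1,
                "foci_count": metrics.foci_count,
                "total_foci_intensity": metrics.total_foci_intensity,
                "total_raw_intensity": float(actin.pixels[cell.mask].sum()),
            }
        )

table = pd.DataFrame(rows)
control = table.loc[table.condition == "control", "total_foci_intensity"]
table["normalized_foci_intensity"] = sf.normalize_to_control(
    table["total_foci_intensity"], control
)
table.to_csv(ROOT / "results" / "group_cells.csv", index=False)

comparisons = sf.compare_groups(
    table, "normalized_foci_intensity", "condition", [("control", "foci_deficient")]
)
comparisons.to_csv(ROOT / "results" / "comparisons.csv", index=False)

row = comparisons.iloc[0]
print(f"{row.measure}: U={row.statistic:.0f}, n={row.n1}/{row.n2}, "
      f"p = {sf.format_p(row.p_two_sided)} ({row.method})")
means = table.groupby("condition").mean(numeric_only=True)
print(f"normalized foci intensity: control "
      f"{means.loc['control', 'normalized_foci_intensity']:.2f}, deficient "
      f"{means.loc['foci_deficient', 'normalized_foci_intensity']:.2f}")
raw_ratio = means.loc["foci_deficient", "total_raw_intensity"] / means.loc["control", "total_raw_intensity"]
print(f"total raw synaptic F-actin in deficient cells is {100 * raw_ratio:.1f}% of control "
      f"(foci carry only a small share of the synaptic signal)")
print("tables -> results/group_cells.csv, comparisons.csv")
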