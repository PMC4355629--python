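#!/usr/bin/env python
"""Fresh/total actin incorporation at foci vs the lamellar surround.

Emulates the barbed-end labeling assay: under a 2x local nucleation boost,
fresh actin per pixel is higher inside foci in every cell.  The boost=1
null is also run and reported; note that on shot-noise-limited synthetic
images the detected-mask selection bias depresses the foci-region
fresh/total ratio slightly but systematically, so the paired ratio test
rejects the null even without a planted effect (see docs/methods.md).
"""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

import synfoci as sf

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260918
N_CELLS = 20

rows = []
for boost in (1.0, 2.0):
    for i in range(N_CELLS):
        params = sf.SynapseParams(seed=SEED + 31 * (i + 1))
        fresh, total, cell, _ = sf.generate_fresh_total_pair(
            params, rate=0.3, foci_nucleation_boost=boost
        )
        foci, _ = sf.detect_foci_pipeline(total, cell)
        rec = sf.fresh_total_ratio(fresh, total, foci, cell)
        rows.append(
            {
                "boost": boost,
                "cell_id": i + 1,
                "fresh_per_px_foci": rec.fresh_per_px_foci,
                "fresh_per_px_surround": rec.fresh_per_px_surround,
                "ratio_foci": rec.ratio_foci,
                "ratio_surround": rec.ratio_surround,
            }
        )

table = pd.DataFrame(rows)
table.to_csv(ROOT / "results" / "fresh_total.csv", index=False)

for boost in (1.0, 2.0):
    sub = table[table.boost == boost]
    p_fresh = sf.format_p(sf.wilcoxon_signed_rank(sub.fresh_per_px_foci, sub.fresh_per_px_surround).p_value)
    p_ratio = sf.format_p(sf.wilcoxon_signed_rank(sub.ratio_foci, sub.ratio_surround).p_value)
    print(f"boost={boost}: fresh/px foci {sub.fresh_per_px_foci.mean():.1f} vs "
          f"surround {sub.fresh_per_px_surround.mean():.1f} (p={p_fresh}); "
          f"ratio foci {sub.ratio_foci.mean():.3f} vs surround {sub.ratio_surround.mean():.3f} "
          f"(p={p_ratio})")
print("per-cell table -> results/fresh_total.csv")
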