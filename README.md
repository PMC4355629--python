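# synfoci

Quantitative analysis of punctate **F-actin foci** at T-cell immunological
synapses from TIRF microscopy images, and of their association with T-cell
receptor (TCR) microclusters.

## The problem

When a T cell engages an activating surface it builds an immunological
synapse whose F-actin is dominated by bright lamellipodial and lamellar
networks. Embedded in that background are discrete, diffraction-limited
actin **foci** that form at TCR microclusters, are nucleated de novo by the
WASP–Arp2/3 pathway, and feed TCR-distal signaling (PLCγ1 activation,
calcium flux). Because the foci carry under 10% of the synaptic F-actin
signal, naive whole-synapse intensity measurements miss them entirely: the
analysis problem is to extract a faint punctate subpopulation from a bright,
radially structured background and to quantify its coupling to a second
channel.

This package re-implements that measurement chain as a tested library with
a ground-truthed synthetic-data generator, so every stage can be validated
against a known answer.

## The method

**Foci extraction** is a percentile rank-filter high-pass. For a raw image
*I*, the background estimate is

    B_p(x) = percentile_p { I(y) : y in W(x) }

with *W(x)* a square moving window of physical size 1.6 × 1.6 µm centered
on *x*, evaluated at every pixel (nearest-rank, reflect padding). The
high-pass image `H = max(I − B, 0)` is thresholded inside the cell
footprint at `mean(H) + k·SD(H)` (k = 2 by default) and 8-connected
components ≥ 4 px become foci. The 50th percentile (median) is the working
point; 25% under-subtracts and inflates the foci mask, 75% over-subtracts
and shrinks it — the `percentile_sweep` operation reproduces this ordering
with the threshold held fixed.

**Colocalization** of a subject channel (TCR, ICAM1, phospho-proteins) with
the foci mask is intensity-weighted per cell:

    fraction = Σ subject over (subject mask ∩ foci mask ∩ cell)
             / Σ subject over (subject mask ∩ cell)

with an object-level variant in which a whole subject cluster counts when
it touches the foci mask. Chance level is estimated by translating the foci
mask by (+5, +5) px with zero fill and recomputing the fraction on the
valid region.

Other readouts: fresh/total actin incorporation ratios inside vs outside
foci (barbed-end labeling assay), kymograph velocimetry (sub-pixel ridge
tracking + Theil–Sen slope, reported in µm/min), line-scan profiles
normalized to their own minimum, F/F0 calcium-trace normalization, nuclear
transcription-factor intensity in the actin-free synapse center, and
Mann–Whitney / Wilcoxon statistics with exact small-sample enumeration.

## Worked example

```python
import synfoci as sf

params = sf.SynapseParams(seed=1)           # 6 µm cell, 20 foci, 20 clusters
actin, clusters, cell, truth = sf.generate_synapse(params)

foci, highpass = sf.detect_foci_pipeline(actin, cell)
metrics = sf.foci_metrics_per_cell(foci, highpass, cell)
print(metrics.foci_count, round(metrics.foci_pixel_fraction, 3))
# 20 0.032

pair = sf.coloc_with_chance(clusters, actin, cell)
print(round(pair.observed.fraction, 3), round(pair.chance.fraction, 3))
# 0.207 0.058
```

All 20 planted foci are recovered on this seed, occupying 3.2% of the
synapse footprint — inside the <10% regime. Half the clusters were planted
on foci: 20.7% of the thresholded cluster intensity overlaps the foci
mask, collapsing to 5.8% after the 5 px shift.

The numbered scripts under `analysis/` run the full story on simulated
cohorts — simulation, detection and the percentile sweep, colocalization
vs the shift null (TCR-like vs ICAM1-like), fresh/total incorporation,
kymograph speeds and calcium, and a control-vs-foci-deficient group
report — writing tables under `results/`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's headline measurements from scratch on seeded
synthetic cohorts (foci counts and pixel fractions, the percentile sweep,
colocalized fractions with their shift control, fresh/total contrast,
recovered speeds, calcium plateau), prints them, and writes the summary
JSON to `--out`.
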