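# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `synfoci` pipeline. It states no empirical result that
the test suite and `scripts/acceptance.py` do not themselves compute.

## Foci extraction by percentile rank filtering

The background of a synaptic TIRF image is estimated per pixel as the
nearest-rank percentile of a square moving window:

- **Percentile semantics.** Element `ceil(p/100 · N)` of the sorted window
  (N = w² samples), with no interpolation. This is exact on integer images
  and is checked pixelwise against a brute-force sorted-window oracle.
- **Window.** 1.6 µm square, converted to pixels as
  `round(1.6 / pixel_size)` and forced to the nearest odd integer ≥ 3 (a
  centered window needs odd width; at the 0.16 µm/px default this is
  11 px). The filter is evaluated at every pixel (subsample ratio 1).
- **Borders.** Reflect (symmetric) padding. Edge-extension alternatives
  darken the estimate at the rim and seed spurious border foci.
- **High-pass.** `max(raw − background, 0)`; fluorescence intensities are
  sums, so negative residuals are clipped.
- **Threshold.** The default is `mean + 2·SD` of the high-pass intensities
  within the cell mask; Otsu and absolute thresholds are available and the
  rule used is part of the detection parameters. Components are 8-connected
  and must cover ≥ 4 px (single-pixel shot noise is not a focus).

**The percentile sweep.** Because the rank filter is monotone in the
percentile, the three high-pass images at p = 25/50/75 are pixelwise
ordered. The `percentile_sweep` operation holds the detection threshold
fixed (computed once from the median high-pass) while varying only the
background percentile, so the foci masks are nested and the foci area is
monotonically decreasing in the percentile by construction. Re-deriving
the adaptive threshold per percentile would confound the comparison — each
high-pass has different statistics — and empirically breaks the ordering
on a minority of images; the sweep is a controlled comparison of the
background model, not three independent end-to-end runs.

## Cell footprints

The original workflow outlined cells by hand. Here `segment_cells` smooths
with a Gaussian (σ = 2 px), thresholds globally by Otsu's method on the
smoothed image, fills holes, labels 8-connected components and discards
regions under 500 px². The threshold derives from the image's own
histogram, so segmentation is invariant to positive rescaling. Cells
touching the image border are kept but flagged: the pixel-shift chance
analysis must know that part of their neighborhood is missing.

## Colocalization and the pixel-shift null

Both channels are processed through the identical rank-filter + threshold
pipeline. Two per-cell estimators are provided:

- **Pixel-level fraction** — thresholded subject intensity inside the
  reference foci mask over the subject's total thresholded intensity.
  This measures geometric mask overlap and is the statistic used for the
  shift-control contrast.
- **Object-level fraction** — a subject connected component (one receptor
  microcluster) counts with its entire intensity when any of its pixels
  touches the reference mask. This is the "fraction of microclusters
  associated with foci" readout. The pixel-level fraction is strictly
  smaller, because a cluster sitting within ~2 px of a focus still only
  partially overlaps the ~2 px detected focus mask; recovery of a planted
  colocalized fraction is therefore validated with the object-level
  estimator.

**Chance control.** The reference (foci) mask is translated by (+5, +5) px
with zero fill — the subject stays put — and the fraction is recomputed on
the intersection of the cell mask with the valid (non-filled) region.
Zero fill with a validity restriction was chosen over circular wrap, which
would import opposite-edge cell structure into the null. A single diagonal
shift is the default; an ensemble over the 8 compass shifts is available
(`shift` argument) but off by default. Shift (0, 0) reproduces the
unshifted result exactly, which is asserted in tests.

## Synthetic synapse scenes

The generator emulates the statistical structure the analyses assume, not
optical physics:

- **Geometry.** A disk footprint of radius 6 µm (default) at 0.16 µm/px.
  The lamellar background is an annular band: a depleted central cSMAC
  disk at 0.3 R carrying 20% of peak intensity, a smooth cosine rise to
  the peak at 0.8 R, and a taper to half-peak at the rim. Peak amplitude
  100 counts.
- **Objects.** Foci are isotropic 2D Gaussians with σ = 1.3 px (≈ 200 nm
  diffraction limit at this pixel size), amplitude 50 counts ≈ 5× the
  shot-noise SD at the lamellar peak, placed uniformly by area over the
  lamellar annulus with ≥ 6 px spacing so that every planted focus remains
  a separate 8-connected component (detected spots extend ~2 px).
  Microclusters are rendered identically in their own channel on a
  diffuse in-footprint background (20 counts).
- **Colocalization truth.** Exactly `round(f · n_clusters)` clusters are
  placed within 2 px of a focus center; the rest are kept ≥ 3 PSF sigmas
  from every focus so the labels are unambiguous. `coloc_fraction=None`
  places clusters independently of the foci (the ICAM1-like null).
- **Noise.** Poisson shot noise on the clean image (gain 1.0) plus
  Gaussian read noise with σ = 2% of the lamellar amplitude, applied last,
  clipped at zero. One seeded RNG stream per scene; placement precedes
  noise in a fixed order, so identical parameters and seed give
  bitwise-identical output.
- **Time-lapses.** Objects move radially inward at a set speed
  (µm/min · frame_interval/60 / pixel_size px per frame); on reaching the
  cSMAC disk the cluster persists in place and the focus amplitude drops
  to zero, mirroring foci extinction in the synapse center. Speed scenes
  place the object at the distal rim (`object_radius_frac`), where
  microclusters actually form, so tracks span several frames at fast
  speeds.
- **Fresh/total pairs.** `total` is background + foci; `fresh` is
  `rate · total` everywhere except within 2 PSF sigmas of a focus center,
  where it is multiplied by the nucleation boost. Noise is drawn
  independently per channel.
- **Calcium traces.** Per-cell step functions (baseline 100, configurable
  fold change at a set rise frame) plus Gaussian noise.

What the generator does **not** model: realistic PSFs (Gibson–Lanni),
photobleaching, cell-shape dynamics or irregular outlines, per-cell
biological variability in foci brightness or background structure, and
channel misregistration. A green recovery test therefore establishes that
the measurement chain is correct and calibrated for shot-noise-limited
data with the stated geometry — not that it is robust to every property
of real synapses.

## Kymographs and speed

Kymographs sample each frame along a line with bilinear interpolation,
averaging 3 px perpendicular to the line (a 1 px line is noisier and
gains nothing). Speed estimation first applies the rank-filter high-pass
to every frame: on raw frames the column argmax locks onto the static
lamellar annulus, whose brightness rivals a focus. Ridge positions are
the per-column argmax refined by a 3-point parabola, and the slope across
frames is fit with Theil–Sen (robust to the bright cSMAC terminus and to
occasional argmax outliers); speed = |slope| · pixel_size · 60 /
frame_interval, in µm/min. A perfectly stationary noise-free ridge yields
exactly 0; with camera noise the argmax jitters, so exact zeros are only
guaranteed without noise.

## Fresh/total incorporation

Per cell, the foci region is the detected foci mask and the surround is
the synapse footprint minus it. Reported are mean fresh intensity per
pixel in each region and the pixelwise fresh/total ratio averaged per
region, excluding pixels whose total intensity is below 5% of the cell
mean (division stability).

**Known bias.** The foci mask is thresholded on the same noisy total
image that enters the ratio denominator, so mask pixels have conditionally
up-fluctuated total values and the foci-region ratio is biased low
(~0.025 at default settings, several times the per-cell standard error
on synthetic data); dim-pixel 1/T convexity adds a smaller opposite-signed
term in the surround. On shot-noise-limited synthetic cohorts the paired
ratio test therefore rejects a true null essentially always — per-cell
estimates average hundreds of pixels, so any systematic method bias is
many standard errors. On real data this bias is swamped by biological
per-cell variability. The boost detection direction (fresh per pixel
higher at foci when nucleation is genuinely boosted) is unaffected.

## Other quantifications

- **Line profiles** are normalized to their own minimum before averaging
  (so the normalized minimum is exactly 1); all channels are sampled at
  identical pixel positions, and lines are resampled to a common length
  before population averaging (mean ± SEM per position).
- **Foci-pixel histograms** divide pixel intensities by the cell's mean
  raw synaptic intensity and report counts normalized both to all synapse
  pixels and to foci pixels only; default 40 bins over [0, 4].
- **Nuclear intensity** uses the connected low-actin region (< 30% of the
  cell's mean actin, inside the 2 px-eroded footprint) containing the cell
  centroid as the nucleus proxy, replacing manual outlining of the
  phalloidin-free center. The threshold fraction and erosion are exposed;
  the default cSMAC of the simulator (20% of peak) deliberately does not
  qualify — a nucleus scenario requires genuine central actin depletion.
- **Calcium** traces are divided by the mean of their first 10 frames
  (baseline window configurable; the acquisition protocol does not pin
  it down).

## Statistics

Unpaired comparisons use the Mann–Whitney U test (the rank-sum test; U
carries half credit for ties, U₁ + U₂ = n₁n₂); paired comparisons use the
Wilcoxon signed-rank test with zero differences dropped. Both report
two-sided p-values:

- **Exact path** — full enumeration of the C(n₁+n₂, n₁) labelings
  (pooled n ≤ 12, tie-free) or of the 2ⁿ sign assignments (n ≤ 15, via a
  subset-sum count over doubled ranks, valid under ties). Two-sidedness is
  symmetric deviation from the null mean; both null distributions are
  symmetric, so this coincides with tail doubling when there are no ties.
- **Approximate path** — normal approximation with tie-corrected variance,
  0.5 continuity correction, and an Edgeworth kurtosis term
  (γ₂(U) = −(6/5)(n₁²+n₂²+n₁n₂+n₁+n₂)/(n₁n₂(n+1)),
  γ₂(W) = −(12/5)(3n²+3n−1)/(n(n+1)(2n+1)); both statistics are
  platykurtic and the plain normal overshoots moderate tails). With the
  correction the two paths agree to well under 0.01 at the crossover
  sizes, and the null rejection rate at α = 0.05 is calibrated (asserted
  over 2000 seeded replicates).

Crossovers (12 pooled / 15 pairs) keep the exact paths interactive-fast.
Summaries are mean ± SEM (SD with the n−1 denominator). No
multiple-testing correction layer is provided, matching the source
workflow. The underlying reports called this test the "Mann–Whitney
unpaired t-test"; it is the Mann–Whitney U.

## Defaults chosen where the source was silent

- Pixel size 0.16 µm/px (typical 100×/EMCCD); every physical conversion
  is parameterized, nothing is hard-coded to this value.
- Foci amplitude and size statistics are not published beyond image
  panels; defaults were chosen to satisfy the documented <10%-of-pixels
  regime and are configuration, not measurement.
- The 5 px shift is interpreted as one simultaneous diagonal displacement;
  axis-wise controls are computable via the `shift` argument.
- Detection threshold rule (`mean + 2·SD`), calcium baseline window (10
  frames), nuclear actin fraction (0.3) and erosion (2 px) are exposed
  parameters recorded with results.
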