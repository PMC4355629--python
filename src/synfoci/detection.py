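"""Percentile rank-filter background subtraction and F-actin foci detection.

The method: estimate the smooth lamellar background of a TIRF image as the
per-pixel percentile (median by default) of a square moving window of
physical size 1.6 x 1.6 µm, subtract it from the raw image to obtain a
high-pass image in which diffraction-limited foci stand out, threshold that
image within the cell footprint, and label the surviving 8-connected
components as foci.  Lower percentiles under-subtract and inflate the foci
mask; higher percentiles over-subtract and shrink it — the median is the
working point, and the percentile is exposed so the sweep can be reproduced.

Percentile semantics are nearest-rank (element ``ceil(p/100 * N)`` of the
sorted window, no interpolation), evaluated at every pixel with reflect
padding at the borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .errors import ParameterError
from .io import CellRegion, Image

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class RankFilterParams:
    """Parameters of the rank-filter detection pipeline.

    percentile:
        Window percentile for background estimation, in (0, 100); 50 is the
        median filter used for all headline quantifications.
    window:
        Side of the square moving window in µm (default 1.6).
    threshold_k:
        The foci threshold is mean + threshold_k * SD of the high-pass
        intensities within the cell mask (``threshold_method="mean_sd"``).
    min_focus_area:
        Connected components smaller than this (px^2) are discarded;
        default 4 suppresses single-pixel shot noise.
    """

    percentile: float = 50.0
    window: float = 1.6
    threshold_k: float = 2.0
    min_focus_area: int = 4
    threshold_method: str = "mean_sd"   # or "otsu", "absolute"
    absolute_threshold: float = 0.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ParameterError("percentile must lie in (0, 100)")
        if self.window <= 0:
            raise ParameterError("window must be positive")
        if self.min_focus_area < 1:
            raise ParameterError("min_focus_area must be >= 1")
        if self.connectivity != 8:
            raise ParameterError("only 8-connectivity is supported")

    def window_px(self, pixel_size: float) -> int:
        """Window width in px: round(window/pixel_size) forced odd, >= 3."""
        w = int(round(self.window / pixel_size))
        if w % 2 == 0:
            w += 1
        if w < 3:
            raise ParameterError(
                f"window {self.window} µm is {w} px at {pixel_size} µm/px; need >= 3"
            )
        return w


@dataclass
class FociSet:
    """Labeled foci mask plus per-focus records for one cell.

    ``label_mask`` holds 0 for background and k for focus k (labels
    consecutive from 1); ``foci`` has one row per focus with columns
    ``focus_id, row, col, area_px, intensity`` (centroid in px, integrated
    intensity in high-pass units).
    """

    label_mask: np.ndarray
    foci: pd.DataFrame
    cell_id: int = 0

    @property
    def n_foci(self) -> int:
        return len(self.foci)

    @property
    def mask(self) -> np.ndarray:
        return self.label_mask > 0

    @property
    def total_intensity(self) -> float:
        return float(self.foci["intensity"].sum())

    def centroids(self) -> np.ndarray:
        return self.foci[["row", "col"]].to_numpy(dtype=float).reshape(-1, 2)


def estimate_background(image: Image, params: RankFilterParams) -> Image:
    """Moving-window nearest-rank percentile background estimate.

    Evaluated at every pixel (subsample ratio 1) with reflect padding, so
    the output is congruent with the input.  Monotone in the percentile:
    p1 < p2 implies output_p1 <= output_p2 pixelwise.
    """
    w = params.window_px(image.pixel_size)
    n = w * w
    # nearest-rank: 1-based index ceil(p/100 * n) -> 0-based for rank_filter
    rank = int(np.ceil(params.percentile / 100.0 * n)) - 1
    bg = ndimage.rank_filter(image.pixels, rank=rank, size=w, mode="reflect")
    return Image(bg, image.pixel_size, image.channel)


def subtract_background(image: Image, background: Image) -> Image:
    """High-pass image: max(image - background, 0) pixelwise."""
    if image.shape != background.shape:
        raise ValueError("image and background shapes differ")
    hp = np.maximum(image.pixels.astype(float) - background.pixels.astype(float), 0.0)
    return Image(hp, image.pixel_size, image.channel)


def highpass(image: Image, params: RankFilterParams | None = None) -> Image:
    """Convenience: rank-filter background estimate followed by subtraction."""
    params = params or RankFilterParams()
    return subtract_background(image, estimate_background(image, params))


def _threshold(hp: np.ndarray, mask: np.ndarray, params: RankFilterParams) -> float:
    vals = hp[mask]
    if params.threshold_method == "mean_sd":
        return float(vals.mean() + params.threshold_k * vals.std(ddof=1))
    if params.threshold_method == "otsu":
        return float(threshold_otsu(vals))
    if params.threshold_method == "absolute":
        return float(params.absolute_threshold)
    raise ParameterError(f"unknown threshold method {params.threshold_method!r}")


def detect_foci(
    highpass_image: Image,
    cell: CellRegion,
    params: RankFilterParams | None = None,
) -> FociSet:
    """Threshold the high-pass image within the cell mask and label foci.

    The threshold is computed from the high-pass intensity distribution
    inside the cell mask (mean + k SD by default); pixels above it are
    labeled by 8-connectivity, components below ``min_focus_area`` are
    dropped, and per-focus integrated intensities are read off the
    high-pass image.
    """
    params = params or RankFilterParams()
    if highpass_image.shape != cell.mask.shape:
        raise ValueError("high-pass image and cell mask shapes differ")
    hp = highpass_image.pixels
    thr = _threshold(hp, cell.mask, params)
    binary = (hp > thr) & cell.mask
    labels, _ = ndimage.label(binary, structure=_EIGHT)
    records = []
    keep = np.zeros_like(labels)
    next_id = 1
    for prop in regionprops(labels, intensity_image=hp):
        if prop.area < params.min_focus_area:
            continue
        keep[labels == prop.label] = next_id
        r, c = prop.centroid_weighted
        records.append(
            {
                "focus_id": next_id,
                "row": float(r),
                "col": float(c),
                "area_px": int(prop.area),
                "intensity": float(prop.image_intensity.sum()),
            }
        )
        next_id += 1
    foci = pd.DataFrame(records, columns=["focus_id", "row", "col", "area_px", "intensity"])
    return FociSet(label_mask=keep, foci=foci, cell_id=cell.cell_id)


def detect_foci_pipeline(
    image: Image,
    cell: CellRegion,
    params: RankFilterParams | None = None,
) -> tuple[FociSet, Image]:
    """Full chain raw -> background -> high-pass -> FociSet.

    Returns the foci and the high-pass image (needed by the downstream
    intensity quantifications).
    """
    params = params or RankFilterParams()
    hp = highpass(image, params)
    return detect_foci(hp, cell, params), hp


def percentile_sweep(
    image: Image,
    cell: CellRegion,
    percentiles: tuple[float, ...] = (25.0, 50.0, 75.0),
    params: RankFilterParams | None = None,
) -> dict[float, FociSet]:
    """Detect foci with background percentiles swept, all else held fixed.

    The sweep varies only the background-estimation percentile; the foci
    threshold is computed once, from the high-pass image at the reference
    percentile (``params.percentile``, the median by default), and applied
    to every member of the sweep.  Re-deriving the threshold per percentile
    would confound the comparison (each high-pass has different statistics).
    Because the rank filter is monotone in the percentile, the resulting
    foci masks are nested: lower percentiles under-subtract and inflate the
    foci area, higher percentiles over-subtract and shrink it.
    """
    params = params or RankFilterParams()
    ref_hp = highpass(image, params)
    thr = _threshold(ref_hp.pixels, cell.mask, params)
    fixed = RankFilterParams(
        percentile=params.percentile,
        window=params.window,
        threshold_method="absolute",
        absolute_threshold=thr,
        min_focus_area=params.min_focus_area,
    )
    out: dict[float, FociSet] = {}
    for p in percentiles:
        hp_p = highpass(
            image,
            RankFilterParams(percentile=p, window=params.window),
        )
        out[p] = detect_foci(hp_p, cell, fixed)
    return out


@dataclass
class CellFociMetrics:
    cell_id: int
    foci_count: int
    total_foci_intensity: float
    total_cell_intensity: float
    foci_pixel_fraction: float


def foci_metrics_per_cell(
    fociset: FociSet, highpass_image: Image, cell: CellRegion
) -> CellFociMetrics:
    """Per-cell summary: focus count, summed foci intensity, total cell
    intensity in the high-pass image, and foci-pixel fraction of the
    synapse footprint."""
    hp = highpass_image.pixels
    return CellFociMetrics(
        cell_id=cell.cell_id,
        foci_count=fociset.n_foci,
        total_foci_intensity=fociset.total_intensity,
        total_cell_intensity=float(hp[cell.mask].sum()),
        foci_pixel_fraction=float(fociset.mask.sum()) / float(cell.mask.sum()),
    )


def normalize_to_control(values, control_values) -> np.ndarray:
    """Divide per-cell values by the mean of the control group.

    This is the convention used for all cross-condition intensity plots:
    each dataset is expressed relative to the average of its experiment's
    control cells.
    """
    control = np.asarray(control_values, dtype=float)
    m = control.mean()
    if not m > 0:
        raise ValueError("control mean must be positive")
    return np.asarray(values, dtype=float) / m


def match_centroids(
    detected: np.ndarray, truth: np.ndarray, radius: float
) -> tuple[int, int, int]:
    """One-to-one match detected centroids to planted centers within a radius.

    Returns ``(n_matched, n_detected, n_truth)``; recall is
    ``n_matched / n_truth`` and precision ``n_matched / n_detected``.
    Matching is optimal one-to-one assignment on the distance matrix with
    pairs farther than ``radius`` forbidden.
    """
    from scipy.optimize import linear_sum_assignment

    detected = np.asarray(detected, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(detected) == 0 or len(truth) == 0:
        return 0, len(detected), len(truth)
    d = np.hypot(
        detected[:, None, 0] - truth[None, :, 0],
        detected[:, None, 1] - truth[None, :, 1],
    )
    cost = np.where(d <= radius, d, 1e9)
    rows, cols = linear_sum_assignment(cost)
    n_matched = int(np.sum(d[rows, cols] <= radius))
    return n_matched, len(detected), len(truth)
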