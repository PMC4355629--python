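"""Line profiles, intensity histograms, fresh/total ratios, kymograph
velocimetry, calcium-trace normalization and nuclear translocation readouts.

These are the secondary quantifications that sit on top of foci detection:
per-line-scan normalized intensity profiles, the foci-pixel intensity
histogram used to validate the detector, the fresh/total actin
incorporation comparison, microcluster speed from kymographs, F/F0 calcium
traces, and mean nuclear intensity inside the actin-free central zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import theilslopes

from .detection import FociSet
from .errors import RidgeError
from .io import CellRegion, Image, TimeLapse

Point = tuple[float, float]


# ---------------------------------------------------------------------------
# line profiles


def sample_line(image: Image, start: Point, end: Point, n_samples: int | None = None) -> np.ndarray:
    """Bilinear samples along the segment start->end (row, col), ~1 px apart."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    length = float(np.hypot(*(end - start)))
    if n_samples is None:
        n_samples = int(np.ceil(length)) + 1
    t = np.linspace(0.0, 1.0, n_samples)
    coords = start[:, None] * (1 - t) + end[:, None] * t
    return ndimage.map_coordinates(image.pixels.astype(float), coords, order=1, mode="nearest")


def normalize_profile(profile: np.ndarray) -> np.ndarray:
    """Divide a profile by its own minimum (so the normalized minimum is 1)."""
    profile = np.asarray(profile, dtype=float)
    m = profile.min()
    if m <= 0:
        raise ValueError("profile minimum must be positive for normalization")
    return profile / m


@dataclass
class LineScan:
    """Raw and min-normalized per-channel profiles over one pixel line."""

    start: Point
    end: Point
    raw: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]


def line_scan(images: dict[str, Image], start: Point, end: Point, n_samples: int | None = None) -> LineScan:
    """Sample all channels at identical pixel positions along one line."""
    raw = {name: sample_line(im, start, end, n_samples) for name, im in images.items()}
    return LineScan(start, end, raw, {name: normalize_profile(p) for name, p in raw.items()})


def line_profile_mean(
    images: dict[str, Image],
    lines: list[tuple[Point, Point]],
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Average min-normalized profiles across lines, per channel.

    All lines are resampled to a common length (the longest line's pixel
    count unless ``n_samples`` is given); each profile is normalized to its
    own minimum before averaging.  Returns a tidy frame with columns
    ``position, channel, mean, sem, n``.
    """
    if n_samples is None:
        lengths = [
            int(np.ceil(np.hypot(e[0] - s[0], e[1] - s[1]))) + 1 for s, e in lines
        ]
        n_samples = max(lengths)
    rows = []
    for name in images:
        profiles = np.array(
            [
                normalize_profile(sample_line(images[name], s, e, n_samples))
                for s, e in lines
            ]
        )
        mean = profiles.mean(axis=0)
        sem = (
            profiles.std(axis=0, ddof=1) / np.sqrt(len(lines))
            if len(lines) > 1
            else np.zeros(n_samples)
        )
        for i in range(n_samples):
            rows.append((i, name, mean[i], sem[i], len(lines)))
    return pd.DataFrame(rows, columns=["position", "channel", "mean", "sem", "n"])


# ---------------------------------------------------------------------------
# foci-pixel intensity histogram


def foci_pixel_histogram(
    raw: Image,
    fociset: FociSet,
    cell: CellRegion,
    n_bins: int = 40,
    intensity_range: tuple[float, float] = (0.0, 4.0),
) -> pd.DataFrame:
    """Histogram of per-pixel intensity, foci pixels vs all synapse pixels.

    Pixel intensities are first divided by the cell's mean raw synaptic
    intensity; counts are reported normalized (a) to the total number of
    synapse pixels and (b) to the number of foci pixels, matching the two
    plotting conventions.  Returns a frame with columns ``bin_left,
    bin_right, region, frac_of_total, frac_of_region``.
    """
    mean_int = float(raw.pixels[cell.mask].mean())
    norm = raw.pixels / mean_int
    edges = np.linspace(*intensity_range, n_bins + 1)
    n_total = int(cell.mask.sum())
    rows = []
    for region_name, region in (("foci", fociset.mask & cell.mask), ("synapse", cell.mask)):
        vals = norm[region]
        counts, _ = np.histogram(vals, bins=edges)
        n_region = max(int(region.sum()), 1)
        for i in range(n_bins):
            rows.append(
                (
                    edges[i],
                    edges[i + 1],
                    region_name,
                    counts[i] / n_total,
                    counts[i] / n_region,
                )
            )
    return pd.DataFrame(
        rows, columns=["bin_left", "bin_right", "region", "frac_of_total", "frac_of_region"]
    )


def average_histograms(per_cell: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean ± SEM of per-cell histograms over a cohort (common bin edges)."""
    stacked = pd.concat(per_cell, keys=range(len(per_cell)), names=["cell"])
    out = (
        stacked.groupby(["bin_left", "bin_right", "region"], as_index=False)
        .agg(
            frac_of_total_mean=("frac_of_total", "mean"),
            frac_of_total_sem=("frac_of_total", "sem"),
            frac_of_region_mean=("frac_of_region", "mean"),
            frac_of_region_sem=("frac_of_region", "sem"),
            n=("frac_of_total", "size"),
        )
    )
    return out


# ---------------------------------------------------------------------------
# fresh / total actin incorporation


@dataclass
class FreshTotalRecord:
    """Per-cell barbed-end labeling summary.

    ``fresh_per_px_*`` are mean fresh-channel intensities per pixel in the
    foci vs the surrounding lamellar region; ``ratio_*`` are the pixelwise
    fresh/total ratios averaged over each region (the per-filament
    polymerization-rate proxy).
    """

    cell_id: int
    fresh_per_px_foci: float
    fresh_per_px_surround: float
    ratio_foci: float
    ratio_surround: float
    n_foci_px: int
    n_surround_px: int


def fresh_total_ratio(
    fresh: Image,
    total: Image,
    fociset: FociSet,
    cell: CellRegion,
    floor_fraction: float = 0.05,
) -> FreshTotalRecord:
    """Fresh-actin incorporation inside foci vs the lamellar surround.

    The surround is the synapse footprint minus the foci pixels.  The
    pixelwise fresh/total ratio excludes pixels whose total intensity falls
    below ``floor_fraction`` of the cell mean (division stability).
    """
    if fresh.shape != total.shape or fresh.shape != cell.mask.shape:
        raise ValueError("channels and mask must be congruent")
    foci_px = fociset.mask & cell.mask
    surround = cell.mask & ~fociset.mask
    if not foci_px.any() or not surround.any():
        raise ValueError("foci and surround regions must both be non-empty")
    f = fresh.pixels.astype(float)
    t = total.pixels.astype(float)
    floor = floor_fraction * float(t[cell.mask].mean())
    ok = t >= floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ok, f / np.where(ok, t, 1.0), np.nan)
    return FreshTotalRecord(
        cell_id=cell.cell_id,
        fresh_per_px_foci=float(f[foci_px].mean()),
        fresh_per_px_surround=float(f[surround].mean()),
        ratio_foci=float(np.nanmean(ratio[foci_px])),
        ratio_surround=float(np.nanmean(ratio[surround])),
        n_foci_px=int(foci_px.sum()),
        n_surround_px=int(surround.sum()),
    )


# ---------------------------------------------------------------------------
# kymographs and speed


def highpass_timelapse(timelapse: TimeLapse, params=None) -> TimeLapse:
    """Rank-filter background subtraction applied frame by frame.

    Kymograph ridge tracking needs the static lamellar background removed —
    its annular peak rivals a focus in brightness and otherwise captures
    the column argmax — and the pipeline's own high-pass is the natural
    suppressor.
    """
    from .detection import highpass

    return TimeLapse(
        [highpass(f, params) for f in timelapse.frames], timelapse.frame_interval
    )


@dataclass
class Kymograph:
    """Position (rows, px along the line) x time (columns, frames) matrix."""

    matrix: np.ndarray
    start: Point
    end: Point
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 2 or self.matrix.shape[1] < 2:
            raise ValueError("kymograph needs >= 2 positions and >= 2 frames")


def build_kymograph(
    timelapse: TimeLapse,
    start: Point,
    end: Point,
    width_px: int = 3,
) -> Kymograph:
    """Sample each frame along a line, averaging ``width_px`` perpendicular
    bilinear samples, and stack the profiles as columns."""
    h, w = timelapse.frames[0].shape
    for p in (start, end):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError(f"line endpoint {p} outside image bounds {(h, w)}")
    start_a = np.asarray(start, float)
    end_a = np.asarray(end, float)
    direction = end_a - start_a
    length = float(np.hypot(*direction))
    if length == 0:
        raise ValueError("line endpoints coincide")
    unit = direction / length
    perp = np.array([-unit[1], unit[0]])
    n_pos = int(np.ceil(length)) + 1
    t = np.linspace(0.0, 1.0, n_pos)
    base = start_a[None, :] * (1 - t)[:, None] + end_a[None, :] * t[:, None]
    offsets = np.linspace(-(width_px - 1) / 2.0, (width_px - 1) / 2.0, width_px)
    cols = []
    for frame in timelapse.frames:
        acc = np.zeros(n_pos)
        for off in offsets:
            pts = base + off * perp[None, :]
            acc += ndimage.map_coordinates(
                frame.pixels.astype(float), pts.T, order=1, mode="nearest"
            )
        cols.append(acc / width_px)
    return Kymograph(
        matrix=np.column_stack(cols),
        start=start,
        end=end,
        pixel_size=timelapse.pixel_size,
        frame_interval=timelapse.frame_interval,
    )


def _parabolic_refine(column: np.ndarray) -> float:
    """Sub-pixel position of the column maximum via 3-point parabola."""
    i = int(np.argmax(column))
    if i == 0 or i == len(column) - 1:
        return float(i)
    y0, y1, y2 = column[i - 1], column[i], column[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(i)
    return float(i + 0.5 * (y0 - y2) / denom)


def estimate_speed(kymo: Kymograph) -> float:
    """Speed of the dominant moving object in µm/min.

    Per-frame ridge positions (column argmax with parabolic sub-pixel
    refinement) are fit with a Theil-Sen robust line over frames; the
    speed is ``|slope| * pixel_size * 60 / frame_interval``.  A perfectly
    stationary ridge yields exactly 0.
    """
    mat = kymo.matrix
    if np.any(np.ptp(mat, axis=0) == 0):
        raise RidgeError("flat kymograph column: no ridge to track")
    positions = np.array([_parabolic_refine(mat[:, t]) for t in range(mat.shape[1])])
    frames = np.arange(mat.shape[1])
    if np.ptp(positions) == 0:
        return 0.0
    slope = theilslopes(positions, frames)[0]
    return abs(slope) * kymo.pixel_size * 60.0 / kymo.frame_interval


# ---------------------------------------------------------------------------
# calcium traces


def normalize_calcium_trace(trace, baseline_frames: int = 10) -> np.ndarray:
    """F/F0: divide every frame by the mean of the first ``baseline_frames``."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or len(trace) <= baseline_frames:
        raise ValueError("trace must be 1D and longer than the baseline window")
    f0 = trace[:baseline_frames].mean()
    if f0 <= 0:
        raise ValueError("baseline mean must be positive")
    return trace / f0


def summarize_calcium(traces: pd.DataFrame, baseline_frames: int = 10) -> pd.DataFrame:
    """Population F/F0 summary: mean ± SEM across cells per frame.

    ``traces`` has one row per cell, one column per frame (the layout
    produced by the calcium-trace generator).
    """
    norm = np.array(
        [normalize_calcium_trace(row, baseline_frames) for row in traces.to_numpy()]
    )
    n = norm.shape[0]
    return pd.DataFrame(
        {
            "frame": np.arange(norm.shape[1]),
            "mean_F_F0": norm.mean(axis=0),
            "sem": norm.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            "n_cells": n,
        }
    )


# ---------------------------------------------------------------------------
# nuclear translocation


@dataclass
class NuclearIntensity:
    cell_id: int
    nuclear_mean: float
    nuclear_mask: np.ndarray


def nuclear_nfat_intensity(
    actin: Image,
    nfat: Image,
    cell: CellRegion,
    actin_fraction: float = 0.3,
    erosion_px: int = 2,
) -> NuclearIntensity:
    """Mean transcription-factor intensity inside the actin-free central zone.

    The nucleus proxy is the connected low-actin region (below
    ``actin_fraction`` of the cell's mean actin intensity, inside the
    eroded cell mask) that contains the cell centroid — the automated
    analogue of outlining the phalloidin-free central area by hand.
    """
    if actin.shape != nfat.shape or actin.shape != cell.mask.shape:
        raise ValueError("channels and mask must be congruent")
    eroded = ndimage.binary_erosion(cell.mask, iterations=erosion_px) if erosion_px else cell.mask
    low = actin.pixels < actin_fraction * float(actin.pixels[cell.mask].mean())
    candidate = low & eroded
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3), bool))
    cr, cc = cell.centroid()
    lab = labels[int(round(cr)), int(round(cc))]
    if n == 0 or lab == 0:
        raise ValueError("no low-actin central region contains the cell centroid")
    mask = labels == lab
    return NuclearIntensity(
        cell_id=cell.cell_id,
        nuclear_mean=float(nfat.pixels[mask].mean()),
        nuclear_mask=mask,
    )
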