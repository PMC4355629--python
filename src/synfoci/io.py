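"""Image data model, TIFF I/O and cell-footprint segmentation.

The carriers used throughout the pipeline are deliberately small:

``Image``
    one fluorescence channel as a 2D grid of nonnegative intensities with a
    physical pixel size (µm/px) attached.
``TimeLapse``
    an ordered list of same-shape ``Image`` frames at a fixed frame interval.
``CellRegion``
    a binary mask delimiting one cell's synapse footprint, the unit of
    per-cell quantification.  In the original workflow these regions were
    drawn by hand; :func:`segment_cells` is the reproducible stand-in.

Coordinates are 0-based ``(row, col)`` with row 0 at the top; masks are
always congruent with the images they annotate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, FormatError

#: Fallback physical pixel size (µm/px), typical of a 100x objective with an
#: EMCCD camera.  Every physical-unit conversion goes through ``pixel_size``,
#: so real data with calibrated metadata never touches this default.
DEFAULT_PIXEL_SIZE = 0.16

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


@dataclass
class Image:
    """A single-channel 2D fluorescence image.

    Parameters
    ----------
    pixels:
        2D array of nonnegative intensities (arbitrary fluorescence units).
    pixel_size:
        Physical size of one pixel in µm.
    channel:
        Free-text fluorophore/channel label.
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("Image requires a non-empty 2D pixel grid")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be nonnegative")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class TimeLapse:
    """An ordered sequence of same-shape frames with a fixed frame interval (s)."""

    frames: list[Image]
    frame_interval: float

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("TimeLapse requires at least 2 frames")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        shape = self.frames[0].shape
        px = self.frames[0].pixel_size
        for f in self.frames[1:]:
            if f.shape != shape or f.pixel_size != px:
                raise ValueError("all frames must share shape and pixel_size")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def pixel_size(self) -> float:
        return self.frames[0].pixel_size


@dataclass
class CellRegion:
    """Binary mask delimiting one cell's synapse footprint."""

    mask: np.ndarray
    cell_id: int
    touches_border: bool = field(default=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("CellRegion mask must be a non-empty 2D binary grid")
        _, n = ndimage.label(self.mask, structure=_EIGHT)
        if n != 1:
            raise ValueError("CellRegion mask must be one 8-connected component")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def centroid(self) -> tuple[float, float]:
        r, c = np.nonzero(self.mask)
        return float(r.mean()), float(c.mean())


def _pixel_size_from_metadata(tf: tifffile.TiffFile) -> float | None:
    """Best-effort pixel size (µm/px) from OME or TIFF resolution tags."""
    if tf.ome_metadata:
        m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', tf.ome_metadata)
        if m:
            return float(m.group(1))
    page = tf.pages[0]
    tag = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if tag is not None and unit is not None:
        num, den = tag.value
        if num:
            px = den / num  # units per pixel
            unit_val = getattr(unit.value, "value", unit.value)
            if unit_val == 3:  # centimeter
                return px * 1e4
            if unit_val == 2:  # inch
                return px * 25.4e3
    return None


def _frame_interval_from_metadata(tf: tifffile.TiffFile) -> float | None:
    if tf.ome_metadata:
        m = re.search(r'TimeIncrement="([0-9.eE+-]+)"', tf.ome_metadata)
        if m:
            return float(m.group(1))
    return None


def load_image_stack(
    path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    channel_names: list[str] | None = None,
):
    """Load a plain or OME TIFF into per-channel Images or TimeLapses.

    Returns one ``Image`` per channel for still images, or one ``TimeLapse``
    per channel when a time axis is present.  Integer pixel data are
    preserved bit-exact.

    The pixel size is taken from the file metadata unless overridden; if
    neither is available a :class:`ConfigurationError` is raised (physical
    units are required downstream).  Likewise the frame interval for
    time-lapse files.
    """
    try:
        tf = tifffile.TiffFile(path)
    except (OSError, ValueError) as exc:  # unreadable / not a TIFF
        raise FormatError(f"cannot read TIFF {path!r}: {exc}") from exc
    with tf:
        series = tf.series[0]
        data = np.asarray(series.asarray())
        axes = series.axes.upper()
        meta_px = _pixel_size_from_metadata(tf)
        meta_dt = _frame_interval_from_metadata(tf)

    px = pixel_size if pixel_size is not None else meta_px
    if px is None:
        raise ConfigurationError(
            "pixel size not present in file metadata; pass pixel_size explicitly"
        )

    if "Y" not in axes or "X" not in axes or axes[-2:] not in ("YX",):
        # tifffile returns row-major YX last for all layouts we support
        if axes[-2:] != "YX":
            raise FormatError(f"unsupported axis layout {axes!r}")
    lead = axes[:-2]
    # squeeze singleton leading axes that carry no information
    keep = [i for i, a in enumerate(lead) if data.shape[i] > 1 or a in "TC"]
    data = data.reshape([data.shape[i] for i in keep] + list(data.shape[-2:]))
    lead = "".join(lead[i] for i in keep)

    for a in lead:
        if a not in "TCZQS":
            raise FormatError(f"unsupported axis {a!r} in layout {axes!r}")
    if "Z" in lead:
        raise FormatError("z-stacks are out of scope; project before loading")
    # unlabeled leading axis: treat as channels
    lead = lead.replace("Q", "C").replace("S", "C")

    if lead == "":
        data = data[None]
        lead = "C"
    if lead == "T":
        data = data[:, None]
        lead = "TC"
    if lead == "C":
        n_c = data.shape[0]
        names = channel_names or [f"ch{i}" for i in range(n_c)]
        return [Image(data[i], pixel_size=px, channel=names[i]) for i in range(n_c)]
    if lead == "CT":
        data = np.moveaxis(data, 0, 1)
        lead = "TC"
    if lead == "TC":
        dt = frame_interval if frame_interval is not None else meta_dt
        if dt is None:
            raise ConfigurationError(
                "frame interval not present in metadata; pass frame_interval explicitly"
            )
        n_t, n_c = data.shape[:2]
        names = channel_names or [f"ch{i}" for i in range(n_c)]
        return [
            TimeLapse(
                [Image(data[t, c], pixel_size=px, channel=names[c]) for t in range(n_t)],
                frame_interval=dt,
            )
            for c in range(n_c)
        ]
    raise FormatError(f"unsupported axis layout {axes!r}")


def save_image(path, images: list[Image], frame_interval: float | None = None) -> None:
    """Write channels (optionally stacked identically-shaped) as an OME TIFF."""
    data = np.stack([im.pixels for im in images])
    px = images[0].pixel_size
    meta = {"axes": "CYX", "PhysicalSizeX": px, "PhysicalSizeY": px}
    if frame_interval is not None:
        meta["TimeIncrement"] = frame_interval
    tifffile.imwrite(path, data, ome=True, metadata=meta)


def save_label_mask(path, regions: list[CellRegion], shape: tuple[int, int]) -> None:
    """Serialize cell regions as a 16-bit label image (0 = background, k = cell k)."""
    labels = np.zeros(shape, dtype=np.uint16)
    for region in regions:
        labels[region.mask] = region.cell_id
    tifffile.imwrite(path, labels)


def segment_cells(
    image: Image,
    min_area: float = 500.0,
    smoothing_sigma: float = 2.0,
) -> list[CellRegion]:
    """Segment cell synapse footprints from a fluorescence channel.

    Gaussian smoothing followed by a global Otsu threshold on the smoothed
    image, hole filling, 8-connected labeling, and a minimum-area filter.
    Deterministic, and invariant to positive rescaling of the intensities
    (the threshold is computed from the image's own histogram).  Cells
    touching the image border are retained but flagged, because shift-based
    chance analysis must exclude zero-filled strips.
    """
    smoothed = ndimage.gaussian_filter(image.pixels.astype(float), smoothing_sigma)
    if np.ptp(smoothed) == 0:
        return []
    mask = smoothed > threshold_otsu(smoothed)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    regions: list[CellRegion] = []
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    next_id = 1
    for k in range(1, n + 1):
        m = labels == k
        if m.sum() < min_area:
            continue
        regions.append(
            CellRegion(mask=m, cell_id=next_id, touches_border=bool((m & border).any()))
        )
        next_id += 1
    return regions
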