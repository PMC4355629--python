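"""Intensity-weighted colocalization with a pixel-shift chance control.

The per-cell statistic is the "fraction colocalized": the thresholded
intensity of a subject channel (TCR, ICAM1, a phospho-protein) that falls
inside the reference F-actin foci mask, divided by the subject's total
thresholded intensity in the same cell.  Both channels are processed
through the identical rank-filter + threshold pipeline first.

The chance level is estimated by translating the reference (actin) foci
mask by a fixed pixel offset — (+5, +5) by default — while holding the
subject fixed, and recomputing the fraction over the region where the
shifted mask is valid (zero-filled strips are excluded rather than wrapped,
which would import opposite-edge cell structure into the null).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import FociSet, RankFilterParams, detect_foci_pipeline
from .io import CellRegion, Image

#: the default chance-control displacement, px (applied to both axes)
DEFAULT_SHIFT = (5, 5)


@dataclass
class ColocResult:
    """Fraction of subject intensity residing in the reference mask, per cell."""

    cell_id: int
    fraction: float
    subject_total_intensity: float
    overlap_intensity: float
    shift: tuple[int, int] | None = None
    empty_subject: bool = False   # set when the denominator was 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


def fraction_colocalized(
    subject: Image,
    subject_mask: np.ndarray,
    reference_mask: np.ndarray,
    cell: CellRegion,
    restrict: np.ndarray | None = None,
    shift: tuple[int, int] | None = None,
) -> ColocResult:
    """Intensity-weighted fraction of the subject signal inside the reference mask.

    ``fraction = sum(subject over subject_mask & reference_mask & cell)
    / sum(subject over subject_mask & cell)``; 0 (flagged) when the
    denominator is 0.  ``restrict`` optionally intersects an extra validity
    region (used by the shift control).
    """
    if subject.shape != cell.mask.shape or subject_mask.shape != reference_mask.shape:
        raise ValueError("subject, masks and cell must be congruent")
    domain = np.asarray(subject_mask, bool) & cell.mask
    if restrict is not None:
        domain &= restrict
    px = subject.pixels
    total = float(px[domain].sum())
    overlap = float(px[domain & np.asarray(reference_mask, bool)].sum())
    if total == 0:
        return ColocResult(cell.cell_id, 0.0, 0.0, 0.0, shift=shift, empty_subject=True)
    return ColocResult(cell.cell_id, overlap / total, total, overlap, shift=shift)


def fraction_objects_colocalized(
    subject: Image,
    subject_labels: np.ndarray,
    reference_mask: np.ndarray,
    cell: CellRegion,
    restrict: np.ndarray | None = None,
    shift: tuple[int, int] | None = None,
) -> ColocResult:
    """Object-level fraction colocalized.

    A subject object (one labeled connected component, e.g. one receptor
    microcluster) counts as colocalized — with its entire thresholded
    intensity — when any of its pixels touches the reference mask.  This is
    the per-cell "fraction of subject microclusters associated with foci"
    readout; the pixel-level :func:`fraction_colocalized` measures the
    geometric overlap instead and is strictly smaller.
    """
    if subject.shape != cell.mask.shape or subject_labels.shape != reference_mask.shape:
        raise ValueError("subject, labels and cell must be congruent")
    domain = (subject_labels > 0) & cell.mask
    if restrict is not None:
        domain &= restrict
    px = subject.pixels
    total = float(px[domain].sum())
    if total == 0:
        return ColocResult(cell.cell_id, 0.0, 0.0, 0.0, shift=shift, empty_subject=True)
    hit_ids = np.unique(subject_labels[domain & np.asarray(reference_mask, bool)])
    hit_ids = hit_ids[hit_ids > 0]
    overlap = float(px[domain & np.isin(subject_labels, hit_ids)].sum())
    return ColocResult(cell.cell_id, overlap / total, total, overlap, shift=shift)


def shift_mask(mask: np.ndarray, shift: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Translate a binary mask by (dr, dc) with zero fill.

    Returns ``(shifted, valid)`` where ``valid`` is True wherever the
    shifted mask carries real (non-fill) data.
    """
    dr, dc = shift
    out = np.zeros_like(mask, dtype=bool)
    valid = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = mask[src_r, src_c]
    valid[dst_r, dst_c] = True
    return out, valid


def chance_colocalization_shift(
    subject: Image,
    subject_mask: np.ndarray,
    reference_mask: np.ndarray,
    cell: CellRegion,
    shift: tuple[int, int] = DEFAULT_SHIFT,
) -> ColocResult:
    """Chance-level colocalization: reference mask translated by ``shift``.

    The fraction is recomputed on the intersection of the cell mask with
    the valid (non-zero-filled) region, so border strips do not dilute the
    null.  ``shift=(0, 0)`` reproduces the unshifted result exactly.
    """
    shifted, valid = shift_mask(np.asarray(reference_mask, bool), shift)
    if not (valid & cell.mask).any():
        raise ValueError("no valid region remains after shift")
    return fraction_colocalized(
        subject, subject_mask, shifted, cell, restrict=valid, shift=shift
    )


@dataclass
class ColocPair:
    """Unshifted and shifted colocalization for one cell.

    ``observed``/``chance`` carry the pixel-level overlap fraction;
    ``observed_objects``/``chance_objects`` the object-level fraction
    (whole subject clusters counted when they touch the reference mask).
    """

    observed: ColocResult
    chance: ColocResult
    observed_objects: ColocResult
    chance_objects: ColocResult
    subject_foci: FociSet
    reference_foci: FociSet


def coloc_with_chance(
    subject: Image,
    reference: Image,
    cell: CellRegion,
    params: RankFilterParams | None = None,
    shift: tuple[int, int] = DEFAULT_SHIFT,
) -> ColocPair:
    """Full per-cell colocalization measurement.

    Both channels are rank-filtered, thresholded and masked independently
    with the same parameters; the subject's thresholded intensity inside
    the reference foci mask is then expressed as a fraction of its total,
    and re-measured against the shifted reference mask for the chance
    level.
    """
    params = params or RankFilterParams()
    subj_foci, subj_hp = detect_foci_pipeline(subject, cell, params)
    ref_foci, _ = detect_foci_pipeline(reference, cell, params)
    observed = fraction_colocalized(subj_hp, subj_foci.mask, ref_foci.mask, cell)
    chance = chance_colocalization_shift(subj_hp, subj_foci.mask, ref_foci.mask, cell, shift)
    obs_obj = fraction_objects_colocalized(subj_hp, subj_foci.label_mask, ref_foci.mask, cell)
    shifted_ref, valid = shift_mask(ref_foci.mask, shift)
    cha_obj = fraction_objects_colocalized(
        subj_hp, subj_foci.label_mask, shifted_ref, cell, restrict=valid, shift=shift
    )
    return ColocPair(
        observed=observed,
        chance=chance,
        observed_objects=obs_obj,
        chance_objects=cha_obj,
        subject_foci=subj_foci,
        reference_foci=ref_foci,
    )
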