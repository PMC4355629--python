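"""Ground-truthed synthetic TIRF-synapse image generator.

The generator emulates the geometry and statistics of an early T-cell
immunological synapse imaged in TIRF: a disk-shaped footprint carrying a
radially structured lamellar F-actin background that is depleted in the
central cSMAC zone, diffraction-limited punctate F-actin foci, a receptor
microcluster channel in which a controlled fraction of clusters sits on
foci, EMCCD-like Poisson + Gaussian camera noise, centripetally moving
objects for time-lapses, paired fresh/total actin channels with a local
nucleation boost, and per-cell calcium traces with a baseline and plateau.

Every generator is a pure function of its parameters and seed; the planted
coordinates, colocalization labels and motion tracks are returned as
:class:`GroundTruth` so detection, colocalization and velocimetry can be
scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import PlacementError
from .io import CellRegion, Image, TimeLapse

#: minimum center-to-center spacing between planted foci (px); detected
#: spots extend ~2 px from their centers, so 6 px keeps every planted focus
#: a separate 8-connected component and the ground-truth count unambiguous
_FOCI_MIN_SEP = 6.0
#: a cluster is "non-colocalized" only if it sits at least this many PSF
#: sigmas from every focus center, so truth labels are unambiguous
_EXCLUSION_SIGMAS = 3.0
_MAX_TRIES = 20000


@dataclass(kw_only=True)
class SynapseParams:
    """Parameters of one synthetic synapse scene.

    The defaults describe the regime the analyses assume: a 6 µm cell at
    0.16 µm/px, ~20 diffraction-limited foci whose amplitude is ~5x the
    shot-noise SD at the lamellar peak, and foci pixels well under 10% of
    the synapse area.
    """

    seed: int
    cell_radius: float = 6.0          # µm
    pixel_size: float = 0.16          # µm/px
    image_size: int = 128             # px (square frame)
    lamellar_amplitude: float = 100.0  # peak lamellar intensity (counts)
    edge_enrichment: float = 1.0       # peak multiplier at 0.8 R
    csmac_radius_frac: float = 0.3     # cSMAC disk radius as fraction of R
    csmac_level: float = 0.2           # cSMAC intensity as fraction of peak
    n_foci: int = 20
    foci_amplitude: float = 50.0       # counts above background
    psf_sigma: float = 1.3             # px
    n_clusters: int = 20
    cluster_amplitude: float = 50.0
    cluster_background: float = 20.0   # diffuse receptor signal inside footprint
    coloc_fraction: float | None = 0.5  # None -> independent placement
    coloc_radius: float = 2.0          # px
    noise: bool = True
    gain: float = 1.0                  # Poisson scaling
    read_sigma: float | None = None    # default 2% of lamellar_amplitude
    #: fix the placement radius of foci (fraction of R) instead of sampling it
    #: uniformly over the lamellar annulus; time-lapse speed scenes use this to
    #: start objects at the distal rim, where microclusters form
    object_radius_frac: float | None = None

    def __post_init__(self) -> None:
        if self.coloc_fraction is not None and not 0 <= self.coloc_fraction <= 1:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.n_foci < 0 or self.n_clusters < 0:
            raise ValueError("object counts must be nonnegative")
        if self.read_sigma is None:
            self.read_sigma = 0.02 * self.lamellar_amplitude

    @property
    def radius_px(self) -> float:
        return self.cell_radius / self.pixel_size

    @property
    def center(self) -> tuple[float, float]:
        c = (self.image_size - 1) / 2.0
        return (c, c)


@dataclass
class GroundTruth:
    """Planted object coordinates, labels and tracks for recovery scoring."""

    cell_center: tuple[float, float]
    radius_px: float
    foci_centers: np.ndarray                       # (n_foci, 2) px
    cluster_centers: np.ndarray                    # (n_clusters, 2) px
    cluster_coloc_labels: np.ndarray               # (n_clusters,) bool
    foci_tracks: np.ndarray | None = None          # (n_foci, n_frames, 2)
    cluster_tracks: np.ndarray | None = None       # (n_clusters, n_frames, 2)
    foci_alive: np.ndarray | None = None           # (n_foci, n_frames) bool
    background: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Long-format truth table (`object_type,frame,row,col,coloc_label`)."""
        rows = []
        if self.foci_tracks is None:
            for r, c in self.foci_centers:
                rows.append(("focus", 0, r, c, -1))
            for (r, c), lab in zip(self.cluster_centers, self.cluster_coloc_labels):
                rows.append(("cluster", 0, r, c, int(lab)))
        else:
            for i, track in enumerate(self.foci_tracks):
                for t, (r, c) in enumerate(track):
                    rows.append((f"focus_{i}", t, r, c, -1))
            for i, track in enumerate(self.cluster_tracks):
                lab = int(self.cluster_coloc_labels[i])
                for t, (r, c) in enumerate(track):
                    rows.append((f"cluster_{i}", t, r, c, lab))
        return pd.DataFrame(rows, columns=["object_type", "frame", "row", "col", "coloc_label"])


def background_profile(params: SynapseParams) -> np.ndarray:
    """Noise-free lamellar background: annular band peaking at 0.8 R with a
    smooth falloff into a depleted central cSMAC disk, zero outside the cell."""
    rr, cc = np.indices((params.image_size, params.image_size), dtype=float)
    r0, c0 = params.center
    r = np.hypot(rr - r0, cc - c0)
    R = params.radius_px
    r_c = params.csmac_radius_frac * R
    r_pk = 0.8 * R
    peak = params.lamellar_amplitude * params.edge_enrichment
    lo = params.csmac_level * peak

    prof = np.zeros_like(r)
    inner = r <= r_c
    prof[inner] = lo
    rise = (r > r_c) & (r < r_pk)
    x = (r[rise] - r_c) / (r_pk - r_c)
    prof[rise] = lo + (peak - lo) * 0.5 * (1 - np.cos(np.pi * x))
    fall = (r >= r_pk) & (r < R)
    x = (r[fall] - r_pk) / (R - r_pk)
    prof[fall] = peak * (1.0 - 0.5 * x)  # tapers to half-peak at the rim
    return prof


def cell_mask(params: SynapseParams) -> CellRegion:
    rr, cc = np.indices((params.image_size, params.image_size), dtype=float)
    r0, c0 = params.center
    mask = np.hypot(rr - r0, cc - c0) < params.radius_px
    return CellRegion(mask=mask, cell_id=1)


def render_spots(
    shape: tuple[int, int],
    centers: np.ndarray,
    amplitudes: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Render isotropic 2D Gaussians amp*exp(-d^2 / 2 sigma^2) at subpixel centers."""
    out = np.zeros(shape, dtype=float)
    if len(centers) == 0:
        return out
    rad = int(np.ceil(6 * sigma))
    for (r, c), amp in zip(np.atleast_2d(centers), np.atleast_1d(amplitudes)):
        r_lo, r_hi = max(0, int(r) - rad), min(shape[0], int(r) + rad + 1)
        c_lo, c_hi = max(0, int(c) - rad), min(shape[1], int(c) + rad + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        out[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(-d2 / (2 * sigma**2))
    return out


def apply_camera_noise(clean: np.ndarray, params: SynapseParams, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise at the given gain plus Gaussian read noise, clipped at 0."""
    if not params.noise:
        return clean.copy()
    shot = rng.poisson(np.maximum(clean, 0) * params.gain) / params.gain
    noisy = shot + rng.normal(0.0, params.read_sigma, size=clean.shape)
    return np.maximum(noisy, 0.0)


def _sample_annulus(
    rng: np.random.Generator,
    params: SynapseParams,
    n: int,
    min_sep: float,
    avoid: np.ndarray | None = None,
    avoid_dist: float = 0.0,
) -> np.ndarray:
    """Rejection-sample n points uniformly (by area) in the lamellar annulus,
    with mutual spacing >= min_sep and distance >= avoid_dist from `avoid`."""
    r0, c0 = params.center
    R = params.radius_px
    r_in = params.csmac_radius_frac * R + 1.0
    r_out = 0.95 * R
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > _MAX_TRIES:
            raise PlacementError(
                f"could not place {n} objects with spacing {min_sep} px "
                f"in annulus [{r_in:.1f}, {r_out:.1f}] px"
            )
        if params.object_radius_frac is not None:
            rad = params.object_radius_frac * R
        else:
            rad = np.sqrt(rng.uniform(r_in**2, r_out**2))
        theta = rng.uniform(0, 2 * np.pi)
        p = (r0 + rad * np.sin(theta), c0 + rad * np.cos(theta))
        if pts and np.min(np.hypot(*(np.array(pts) - p).T)) < min_sep:
            continue
        if avoid is not None and len(avoid) and np.min(np.hypot(*(avoid - p).T)) < avoid_dist:
            continue
        pts.append(p)
    return np.array(pts).reshape(n, 2)


def _place_objects(params: SynapseParams, rng: np.random.Generator):
    """Foci and cluster centers plus per-cluster colocalization labels."""
    foci = _sample_annulus(rng, params, params.n_foci, _FOCI_MIN_SEP)
    n = params.n_clusters
    labels = np.zeros(n, dtype=bool)
    if params.coloc_fraction is None:
        clusters = _sample_annulus(rng, params, n, 2.0)
        if len(foci) and n:
            d = np.min(
                np.hypot(
                    foci[:, None, 0] - clusters[None, :, 0],
                    foci[:, None, 1] - clusters[None, :, 1],
                ),
                axis=0,
            )
            labels = d <= params.coloc_radius
        return foci, clusters, labels

    n_co = int(round(params.coloc_fraction * n))
    coloc_pts = np.zeros((0, 2))
    if n_co:
        if not len(foci):
            raise PlacementError("colocalized clusters requested but n_foci == 0")
        host = rng.choice(len(foci), size=n_co, replace=n_co > len(foci))
        rad = params.coloc_radius * np.sqrt(rng.uniform(0, 1, n_co))
        theta = rng.uniform(0, 2 * np.pi, n_co)
        coloc_pts = foci[host] + np.column_stack([rad * np.sin(theta), rad * np.cos(theta)])
    far_pts = _sample_annulus(
        rng, params, n - n_co, 2.0, avoid=foci, avoid_dist=_EXCLUSION_SIGMAS * params.psf_sigma
    )
    clusters = np.vstack([coloc_pts, far_pts])
    labels[:n_co] = True
    return foci, clusters, labels


def generate_synapse(params: SynapseParams):
    """One still synapse scene.

    Returns ``(actin, cluster_channel, cell, truth)``.  The actin channel is
    the lamellar background plus Gaussian foci; the cluster channel is a
    diffuse in-footprint signal plus Gaussian microclusters, of which exactly
    ``round(coloc_fraction * n_clusters)`` sit within ``coloc_radius`` of a
    focus center (unless ``coloc_fraction is None``, meaning placement is
    independent of the foci).  Noise is applied last; identical seeds give
    bitwise-identical output.
    """
    rng = np.random.default_rng(params.seed)
    foci, clusters, labels = _place_objects(params, rng)
    bg = background_profile(params)
    cell = cell_mask(params)

    shape = (params.image_size, params.image_size)
    actin_clean = bg + render_spots(shape, foci, np.full(len(foci), params.foci_amplitude), params.psf_sigma)
    clus_clean = params.cluster_background * cell.mask + render_spots(
        shape, clusters, np.full(len(clusters), params.cluster_amplitude), params.psf_sigma
    )
    actin = Image(apply_camera_noise(actin_clean, params, rng), params.pixel_size, "actin")
    clus = Image(apply_camera_noise(clus_clean, params, rng), params.pixel_size, "clusters")
    truth = GroundTruth(
        cell_center=params.center,
        radius_px=params.radius_px,
        foci_centers=foci,
        cluster_centers=clusters,
        cluster_coloc_labels=labels,
        background=bg,
    )
    return actin, clus, cell, truth


def generate_timelapse(
    params: SynapseParams,
    speed: float,
    n_frames: int,
    frame_interval: float,
):
    """Time-lapse with clusters (and their foci) moving radially inward.

    Per-frame displacement is ``speed * frame_interval / 60 / pixel_size``
    px (speed in µm/min, interval in s).  Objects reaching the cSMAC disk
    stop there; the cluster persists while the focus is extinguished
    (amplitude set to 0), mirroring foci disappearance in the cSMAC.

    Returns ``({"actin": TimeLapse, "clusters": TimeLapse}, cell, truth)``.
    """
    if speed < 0:
        raise ValueError("speed must be nonnegative")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(params.seed)
    foci, clusters, labels = _place_objects(params, rng)
    bg = background_profile(params)
    cell = cell_mask(params)
    shape = (params.image_size, params.image_size)
    center = np.array(params.center)
    r_stop = params.csmac_radius_frac * params.radius_px
    step = speed * frame_interval / 60.0 / params.pixel_size  # px per frame

    def advance(pts: np.ndarray, t: int) -> tuple[np.ndarray, np.ndarray]:
        """Positions at frame t and a flag for having reached the cSMAC."""
        if len(pts) == 0:
            return pts.copy(), np.zeros(0, dtype=bool)
        vec = pts - center
        r = np.hypot(vec[:, 0], vec[:, 1])
        newr = np.maximum(r - step * t, r_stop)
        stopped = (r - step * t) <= r_stop
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r[:, None] > 0, vec / np.maximum(r, 1e-12)[:, None], 0.0)
        return center + unit * newr[:, None], stopped

    foci_tracks = np.zeros((len(foci), n_frames, 2))
    clus_tracks = np.zeros((len(clusters), n_frames, 2))
    foci_alive = np.ones((len(foci), n_frames), dtype=bool)
    actin_frames, clus_frames = [], []
    for t in range(n_frames):
        f_pos, f_stopped = advance(foci, t)
        c_pos, _ = advance(clusters, t)
        foci_tracks[:, t] = f_pos
        clus_tracks[:, t] = c_pos
        foci_alive[:, t] = ~f_stopped
        amps = np.where(f_stopped, 0.0, params.foci_amplitude)
        actin_clean = bg + render_spots(shape, f_pos, amps, params.psf_sigma)
        clus_clean = params.cluster_background * cell.mask + render_spots(
            shape, c_pos, np.full(len(c_pos), params.cluster_amplitude), params.psf_sigma
        )
        actin_frames.append(
            Image(apply_camera_noise(actin_clean, params, rng), params.pixel_size, "actin")
        )
        clus_frames.append(
            Image(apply_camera_noise(clus_clean, params, rng), params.pixel_size, "clusters")
        )
    lapses = {
        "actin": TimeLapse(actin_frames, frame_interval),
        "clusters": TimeLapse(clus_frames, frame_interval),
    }
    truth = GroundTruth(
        cell_center=params.center,
        radius_px=params.radius_px,
        foci_centers=foci,
        cluster_centers=clusters,
        cluster_coloc_labels=labels,
        foci_tracks=foci_tracks,
        cluster_tracks=clus_tracks,
        foci_alive=foci_alive,
        background=bg,
    )
    return lapses, cell, truth


def foci_footprint_mask(params: SynapseParams, truth: GroundTruth) -> np.ndarray:
    """Pixels within 2 PSF sigmas of any planted focus center."""
    shape = (params.image_size, params.image_size)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.indices(shape, dtype=float)
    for r, c in truth.foci_centers:
        mask |= (rr - r) ** 2 + (cc - c) ** 2 <= (2 * params.psf_sigma) ** 2
    return mask


def generate_fresh_total_pair(
    params: SynapseParams,
    rate: float = 0.3,
    foci_nucleation_boost: float = 1.0,
):
    """Paired fresh/total actin channels for the barbed-end labeling assay.

    ``total`` is background + foci; ``fresh`` is ``rate * total`` everywhere
    except inside foci footprints, where it is ``rate * boost * total``.
    ``boost = 1`` is the null of equal per-filament polymerization rate;
    ``boost > 1`` models preferential fresh-subunit incorporation at foci.
    Noise is drawn independently for the two channels.
    """
    if not 0 < rate <= 1:
        raise ValueError("rate must lie in (0, 1]")
    if foci_nucleation_boost < 1:
        raise ValueError("boost must be >= 1")
    rng = np.random.default_rng(params.seed)
    foci, clusters, labels = _place_objects(params, rng)
    bg = background_profile(params)
    cell = cell_mask(params)
    shape = (params.image_size, params.image_size)
    truth = GroundTruth(
        cell_center=params.center,
        radius_px=params.radius_px,
        foci_centers=foci,
        cluster_centers=clusters,
        cluster_coloc_labels=labels,
        background=bg,
    )
    total_clean = bg + render_spots(
        shape, foci, np.full(len(foci), params.foci_amplitude), params.psf_sigma
    )
    fresh_clean = rate * total_clean
    if foci_nucleation_boost != 1.0:
        fp = foci_footprint_mask(params, truth)
        fresh_clean = np.where(fp, rate * foci_nucleation_boost * total_clean, fresh_clean)
    fresh = Image(apply_camera_noise(fresh_clean, params, rng), params.pixel_size, "fresh")
    total = Image(apply_camera_noise(total_clean, params, rng), params.pixel_size, "total")
    return fresh, total, cell, truth


def generate_calcium_traces(
    n_cells: int = 30,
    baseline: float = 100.0,
    fold_change: float = 2.5,
    rise_frame: int = 10,
    n_frames: int = 60,
    noise_sigma: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell calcium-indicator traces: baseline, then a plateau at
    ``baseline * fold_change`` from ``rise_frame`` on, plus Gaussian noise.

    Returns a DataFrame of shape (n_cells, n_frames), one row per cell.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    rng = np.random.default_rng(seed)
    clean = np.full((n_cells, n_frames), baseline)
    clean[:, rise_frame:] = baseline * fold_change
    traces = clean + rng.normal(0.0, noise_sigma, size=clean.shape)
    return pd.DataFrame(
        traces,
        index=pd.RangeIndex(n_cells, name="cell_id"),
        columns=pd.RangeIndex(n_frames, name="frame"),
    )


def cohort(params: SynapseParams, n_cells: int, **kwargs):
    """Yield (actin, clusters, cell, truth) for n_cells scenes with
    per-cell seeds derived deterministically from params.seed."""
    for i in range(n_cells):
        yield generate_synapse(replace(params, seed=params.seed + 7919 * (i + 1), **kwargs))
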