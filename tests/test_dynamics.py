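import numpy as np
import pandas as pd
import pytest

from synfoci import (
    CellRegion,
    Image,
    SynapseParams,
    TimeLapse,
    build_kymograph,
    detect_foci_pipeline,
    estimate_speed,
    foci_metrics_per_cell,
    foci_pixel_histogram,
    fresh_total_ratio,
    generate_synapse,
    line_profile_mean,
    normalize_calcium_trace,
    nuclear_nfat_intensity,
    summarize_calcium,
)
from synfoci.dynamics import Kymograph, normalize_profile, sample_line
from synfoci.errors import RidgeError
from synfoci.simulate import background_profile, cell_mask, render_spots


class TestLineProfiles:
    def test_constant_line_normalizes_to_one(self):
        img = Image(np.full((16, 16), 5.0))
        out = line_profile_mean({"a": img}, [((2, 2), (2, 12))])
        assert np.allclose(out["mean"], 1.0) and np.allclose(out["sem"], 0.0)

    def test_min_normalization(self):
        assert np.allclose(normalize_profile([2, 4, 8]), [1, 2, 4])
        with pytest.raises(ValueError):
            normalize_profile([0.0, 1.0])

    def test_mean_and_sem_arithmetic(self):
        # scans [1,2] and [2,6] -> normalized [1,2] and [1,3]
        img = Image(np.array([[1.0, 2.0], [2.0, 6.0]]))
        out = line_profile_mean({"a": img}, [((0, 0), (0, 1)), ((1, 0), (1, 1))])
        assert np.allclose(out["mean"], [1.0, 2.5])
        assert np.allclose(out["sem"], [0.0, 0.5])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        pixels = rng.uniform(1, 10, (32, 32))
        lines = [((4, 4), (4, 28)), ((10, 4), (10, 28))]
        a = line_profile_mean({"x": Image(pixels)}, lines)
        b = line_profile_mean({"x": Image(pixels * 13.7)}, lines)
        assert np.allclose(a["mean"], b["mean"]) and np.allclose(a["sem"], b["sem"])

    def test_channels_sampled_at_identical_positions(self):
        rr = np.tile(np.arange(16.0), (16, 1))
        out = line_profile_mean(
            {"a": Image(rr + 1), "b": Image(2 * rr + 2)}, [((3, 1), (3, 14))]
        )
        a = out[out.channel == "a"]["mean"].to_numpy()
        b = out[out.channel == "b"]["mean"].to_numpy()
        assert np.allclose(a, b)  # both normalize to the same ramp


class TestFociPixelHistogram:
    def test_uniform_image_single_bin(self):
        mask = np.zeros((32, 32), bool); mask[4:-4, 4:-4] = True
        cell = CellRegion(mask=mask, cell_id=1)
        fs, hp = detect_foci_pipeline(Image(np.full((32, 32), 9.0), pixel_size=0.32), cell)
        hist = foci_pixel_histogram(Image(np.full((32, 32), 9.0)), fs, cell, n_bins=8, intensity_range=(0, 2))
        syn = hist[hist.region == "synapse"]
        occupied = syn[syn.frac_of_total > 0]
        assert len(occupied) == 1
        assert occupied.iloc[0].bin_left <= 1.0 < occupied.iloc[0].bin_right

    def test_foci_mass_identity(self, default_params):
        actin, _, cell, _ = generate_synapse(default_params)
        fs, hp = detect_foci_pipeline(actin, cell)
        m = foci_metrics_per_cell(fs, hp, cell)
        hist = foci_pixel_histogram(actin, fs, cell, n_bins=60, intensity_range=(0, 6))
        foci_mass = hist[hist.region == "foci"].frac_of_total.sum()
        assert foci_mass == pytest.approx(m.foci_pixel_fraction, abs=1e-9)


class TestFreshTotalRatio:
    def test_exact_scaling_gives_equal_ratios(self, default_params):
        actin, _, cell, _ = generate_synapse(default_params)
        fs, _ = detect_foci_pipeline(actin, cell)
        total = actin
        fresh = Image(0.5 * actin.pixels, actin.pixel_size)
        rec = fresh_total_ratio(fresh, total, fs, cell)
        assert rec.ratio_foci == pytest.approx(0.5) and rec.ratio_surround == pytest.approx(0.5)
        # fresh per px tracks total: higher in foci iff total higher there
        assert rec.fresh_per_px_foci > rec.fresh_per_px_surround

    def test_empty_foci_region_raises(self):
        mask = np.zeros((32, 32), bool); mask[4:-4, 4:-4] = True
        cell = CellRegion(mask=mask, cell_id=1)
        fs, _ = detect_foci_pipeline(Image(np.zeros((32, 32)), pixel_size=0.32), cell)
        img = Image(np.ones((32, 32)))
        with pytest.raises(ValueError):
            fresh_total_ratio(img, img, fs, cell)


def _moving_spot_lapse(shift_per_frame=1.0, n_frames=10, noise=None):
    frames = []
    rng = np.random.default_rng(0)
    for t in range(n_frames):
        spot = render_spots((40, 60), np.array([[20.0, 8.0 + shift_per_frame * t]]), np.array([100.0]), 1.3)
        if noise:
            spot = np.maximum(spot + rng.normal(0, noise, spot.shape), 0)
        frames.append(Image(spot, pixel_size=0.16))
    return TimeLapse(frames, frame_interval=5.0)


class TestKymograph:
    def test_static_image_gives_identical_columns(self):
        tl = _moving_spot_lapse(0.0, 5)
        k = build_kymograph(tl, (20, 2), (20, 57))
        assert np.allclose(k.matrix, k.matrix[:, :1])

    def test_matrix_dimensions(self):
        tl = _moving_spot_lapse(0.0, 7)
        k = build_kymograph(tl, (20, 2), (20, 57))
        assert k.matrix.shape == (int(np.ceil(55)) + 1, 7)

    def test_moving_spot_forms_diagonal_ridge(self):
        tl = _moving_spot_lapse(1.0, 10)
        k = build_kymograph(tl, (20, 2), (20, 57))
        ridge = np.argmax(k.matrix, axis=0)
        assert np.allclose(np.diff(ridge), 1)

    def test_line_outside_bounds_raises(self):
        tl = _moving_spot_lapse(0.0, 3)
        with pytest.raises(ValueError):
            build_kymograph(tl, (20, 2), (20, 99))


class TestEstimateSpeed:
    def test_stationary_spot_is_exactly_zero(self):
        k = build_kymograph(_moving_spot_lapse(0.0, 8), (20, 2), (20, 57))
        assert estimate_speed(k) == 0.0

    def test_one_px_per_frame_arithmetic(self):
        # 1 px/frame at 0.16 µm and 5 s -> 0.16 * 12 = 1.92 µm/min
        k = build_kymograph(_moving_spot_lapse(1.0, 12), (20, 2), (20, 57))
        assert estimate_speed(k) == pytest.approx(1.92, rel=0.02)

    def test_direction_reversal_invariance(self):
        tl = _moving_spot_lapse(1.0, 12, noise=2.0)
        fwd = estimate_speed(build_kymograph(tl, (20, 2), (20, 57)))
        rev = estimate_speed(build_kymograph(tl, (20, 57), (20, 2)))
        assert fwd == pytest.approx(rev, rel=1e-6)

    def test_flat_kymograph_raises(self):
        with pytest.raises(RidgeError):
            estimate_speed(
                Kymograph(np.zeros((10, 5)), (0, 0), (0, 9), 0.16, 5.0)
            )


class TestCalcium:
    def test_constant_trace_normalizes_to_one(self):
        assert np.allclose(normalize_calcium_trace(np.full(30, 77.0)), 1.0)

    def test_plateau_fold_change(self):
        trace = np.r_[np.full(10, 100.0), np.full(20, 250.0)]
        norm = normalize_calcium_trace(trace, baseline_frames=10)
        assert np.allclose(norm[10:], 2.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            normalize_calcium_trace(np.zeros(5), baseline_frames=10)
        with pytest.raises(ValueError):
            normalize_calcium_trace(np.zeros(30), baseline_frames=10)

    def test_population_summary_shape(self):
        traces = pd.DataFrame(np.tile(np.r_[np.full(10, 100.0), np.full(10, 300.0)], (4, 1)))
        summ = summarize_calcium(traces)
        assert np.allclose(summ["mean_F_F0"][10:], 3.0)
        assert (summ["n_cells"] == 4).all()


class TestNuclearIntensity:
    def _scene(self):
        p = SynapseParams(seed=11, n_foci=0, noise=False, csmac_level=0.02)
        bg = background_profile(p)
        cell = cell_mask(p)
        return p, Image(bg, p.pixel_size), cell

    def test_uniform_nfat_returns_its_level(self):
        p, actin, cell = self._scene()
        nfat = Image(np.full(actin.shape, 3.0))
        assert nuclear_nfat_intensity(actin, nfat, cell).nuclear_mean == pytest.approx(3.0)

    def test_enriched_center_detected(self):
        p, actin, cell = self._scene()
        res0 = nuclear_nfat_intensity(actin, Image(np.ones(actin.shape)), cell)
        nfat = np.where(res0.nuclear_mask, 10.0, 1.0)
        res = nuclear_nfat_intensity(actin, Image(nfat), cell)
        assert res.nuclear_mean == pytest.approx(10.0)

    def test_translocation_series_monotone(self):
        p, actin, cell = self._scene()
        ref = nuclear_nfat_intensity(actin, Image(np.ones(actin.shape)), cell)
        npx = ref.nuclear_mask.sum()
        cyt_px = cell.area_px - npx
        means = []
        for frac in (0.2, 0.5, 0.8):
            img = np.where(ref.nuclear_mask, 1000 * frac / npx, 1000 * (1 - frac) / cyt_px)
            means.append(nuclear_nfat_intensity(actin, Image(img * cell.mask), cell).nuclear_mean)
        assert means[0] < means[1] < means[2]

    def test_no_central_depletion_raises(self):
        p = SynapseParams(seed=11, n_foci=0, noise=False, csmac_level=0.9)
        cell = cell_mask(p)
        actin = Image(background_profile(p), p.pixel_size)
        with pytest.raises(ValueError):
            nuclear_nfat_intensity(actin, Image(np.ones(actin.shape)), cell)
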