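from dataclasses import replace

import numpy as np
import pytest

from synfoci import (
    CellRegion,
    Image,
    RankFilterParams,
    SynapseParams,
    detect_foci,
    detect_foci_pipeline,
    estimate_background,
    foci_metrics_per_cell,
    generate_synapse,
    highpass,
    match_centroids,
    normalize_to_control,
    percentile_sweep,
    subtract_background,
)
from synfoci.errors import ParameterError
from synfoci.simulate import background_profile, cell_mask, render_spots

from conftest import brute_force_rank_filter

# pixel size at which the default window maps to small test windows
PX3 = 1.6 / 3  # 3 px window


class TestEstimateBackground:
    def test_constant_image_is_fixed_point(self):
        img = Image(np.full((16, 16), 7.0), pixel_size=PX3)
        for p in (25, 50, 75):
            bg = estimate_background(img, RankFilterParams(percentile=p))
            assert np.all(bg.pixels == 7.0)

    def test_isolated_impulse_is_rejected_by_median(self):
        pixels = np.zeros((8, 8))
        pixels[4, 4] = 100.0
        bg = estimate_background(Image(pixels, pixel_size=PX3), RankFilterParams(percentile=50))
        assert np.all(bg.pixels == 0.0)

    @pytest.mark.parametrize("percentile", [25, 50, 75])
    @pytest.mark.parametrize("w", [3, 5, 11])
    def test_matches_brute_force_oracle(self, percentile, w):
        rng = np.random.default_rng(percentile * w)
        pixels = rng.integers(0, 255, size=(16, 16)).astype(float)
        img = Image(pixels, pixel_size=1.6 / w)
        bg = estimate_background(img, RankFilterParams(percentile=percentile))
        oracle = brute_force_rank_filter(pixels, percentile, w)
        assert np.array_equal(bg.pixels, oracle)

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(11)
        img = Image(rng.integers(0, 255, size=(20, 20)).astype(float), pixel_size=PX3)
        b25 = estimate_background(img, RankFilterParams(percentile=25)).pixels
        b50 = estimate_background(img, RankFilterParams(percentile=50)).pixels
        b75 = estimate_background(img, RankFilterParams(percentile=75)).pixels
        assert np.all(b25 <= b50) and np.all(b50 <= b75)

    def test_window_too_small_raises(self):
        img = Image(np.ones((8, 8)), pixel_size=1.6)  # 1 px window
        with pytest.raises(ParameterError):
            estimate_background(img, RankFilterParams())

    def test_window_rounds_to_odd(self):
        assert RankFilterParams().window_px(0.16) == 11
        assert RankFilterParams(window=1.0).window_px(0.2) == 5
        assert RankFilterParams(window=0.8).window_px(0.2) == 5  # 4 -> 5


class TestSubtractBackground:
    def test_identity_input_gives_zero(self):
        img = Image(np.full((4, 4), 3.0))
        assert np.all(subtract_background(img, img).pixels == 0.0)

    def test_negative_differences_clip_to_zero(self):
        img = Image(np.full((4, 4), 5.0))
        bg = Image(np.full((4, 4), 8.0))
        assert np.all(subtract_background(img, bg).pixels == 0.0)

    def test_impulse_on_zero_background_is_retained(self):
        pixels = np.zeros((4, 4))
        pixels[2, 2] = 100.0
        out = subtract_background(Image(pixels), Image(np.zeros((4, 4))))
        assert out.pixels[2, 2] == 100.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            subtract_background(Image(np.ones((4, 4))), Image(np.ones((4, 5))))


def _flat_cell(shape=(64, 64)):
    mask = np.zeros(shape, bool)
    mask[4:-4, 4:-4] = True
    return CellRegion(mask=mask, cell_id=1)


class TestDetectFoci:
    def test_zero_highpass_gives_empty_set(self):
        fs = detect_foci(Image(np.zeros((64, 64))), _flat_cell())
        assert fs.n_foci == 0 and not fs.mask.any()

    def test_single_planted_spot_centroid_accuracy(self):
        # flat background with unit-SD noise, spot amplitude 5x that SD
        rng = np.random.default_rng(2)
        background = rng.normal(10.0, 1.0, (64, 64))
        spot = render_spots((64, 64), np.array([[30.3, 33.7]]), np.array([5.0]), 1.3)
        fs = detect_foci(Image(background + spot), _flat_cell())
        assert fs.n_foci == 1
        r, c = fs.centroids()[0]
        assert np.hypot(r - 30.3, c - 33.7) < 0.5

    def test_connectivity_merging(self):
        far = render_spots((64, 64), np.array([[20, 20], [20, 30]]), np.full(2, 50.0), 1.3)
        near = render_spots((64, 64), np.array([[40, 20], [40, 22]]), np.full(2, 50.0), 1.3)
        fs = detect_foci(Image(far + near), _flat_cell())
        # 10 px apart -> two foci; 2 px apart -> one merged focus
        assert fs.n_foci == 3

    def test_empty_cell_region_rejected(self):
        with pytest.raises(ValueError):
            CellRegion(mask=np.zeros((8, 8), bool), cell_id=1)

    def test_shift_covariance(self):
        """Translating image and mask together translates the centroids."""
        p = SynapseParams(seed=21, image_size=100)
        actin, _, cell, _ = generate_synapse(p)
        fs0, _ = detect_foci_pipeline(actin, cell)
        shifted = np.roll(actin.pixels, (7, -5), axis=(0, 1))
        smask = np.roll(cell.mask, (7, -5), axis=(0, 1))
        fs1, _ = detect_foci_pipeline(
            Image(shifted, actin.pixel_size), CellRegion(mask=smask, cell_id=1)
        )
        c0 = fs0.centroids() + np.array([7.0, -5.0])
        m, nd, nt = match_centroids(fs1.centroids(), c0, radius=0.1)
        assert m == nt == nd

    def test_bright_neighborhood_does_not_preclude_detection(self):
        """Foci on the high-intensity lamellar annulus are recovered as well
        as foci in dim regions."""
        def recall_at(radius_frac, seed):
            p = SynapseParams(seed=seed, n_foci=10, n_clusters=0,
                              object_radius_frac=radius_frac)
            actin, _, cell, truth = generate_synapse(p)
            fs, _ = detect_foci_pipeline(actin, cell)
            m, _, nt = match_centroids(fs.centroids(), truth.foci_centers, 2.0)
            return m / nt

        bright = np.mean([recall_at(0.8, 30 + i) for i in range(5)])
        dim = np.mean([recall_at(0.45, 60 + i) for i in range(5)])
        assert bright >= dim - 0.1

    def test_labels_consecutive_and_intensity_conserved(self, default_params):
        actin, _, cell, _ = generate_synapse(default_params)
        fs, hp = detect_foci_pipeline(actin, cell)
        assert sorted(np.unique(fs.label_mask))[1:] == list(fs.foci["focus_id"])
        total_from_mask = hp.pixels[fs.mask].sum()
        assert fs.total_intensity == pytest.approx(total_from_mask, rel=1e-9)


class TestPercentileSweep:
    def test_foci_area_monotone_in_percentile(self):
        for seed in range(3):
            p = SynapseParams(seed=500 + seed)
            actin, _, cell, _ = generate_synapse(p)
            sweep = percentile_sweep(actin, cell)
            a25, a50, a75 = (int(sweep[q].mask.sum()) for q in (25.0, 50.0, 75.0))
            assert a25 >= a50 >= a75


class TestMetricsAndNormalization:
    def test_empty_fociset_metrics(self):
        cell = _flat_cell()
        fs = detect_foci(Image(np.zeros((64, 64))), cell)
        m = foci_metrics_per_cell(fs, Image(np.zeros((64, 64))), cell)
        assert m.foci_count == 0 and m.total_foci_intensity == 0 and m.foci_pixel_fraction == 0

    def test_planted_count_recovered(self):
        p = SynapseParams(seed=88)
        actin, _, cell, truth = generate_synapse(p)
        fs, hp = detect_foci_pipeline(actin, cell)
        m = foci_metrics_per_cell(fs, hp, cell)
        assert m.foci_count == pytest.approx(p.n_foci, abs=2)
        assert m.foci_pixel_fraction < 0.10

    def test_normalize_to_control(self):
        assert normalize_to_control([2, 4], [1, 3]) == pytest.approx([1.0, 2.0])
        ctrl = np.array([3.0, 5.0, 7.0])
        assert normalize_to_control(ctrl, ctrl).mean() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            normalize_to_control([1.0], [0.0, 0.0])
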