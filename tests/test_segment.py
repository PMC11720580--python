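import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from microquant import segment
from microquant.segment import (
    SeedSet,
    SegmentationParams,
    bradley_threshold,
    filter_by_area,
    integral_image,
    label_components,
    select_by_seeds,
    tune_parameters,
    window_mean,
)


def brute_force_bradley(img, w, s):
    """Naive per-pixel evaluation of the threshold rule (the oracle)."""
    h, wid = img.shape
    half = w // 2
    out = np.zeros_like(img, dtype=bool)
    for i in range(h):
        for j in range(wid):
            win = img[max(i - half, 0) : i + half + 1, max(j - half, 0) : j + half + 1]
            out[i, j] = img[i, j] > (1.0 - s) * win.mean()
    return out


class TestIntegralImage:
    def test_2x2_example(self):
        S = integral_image(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert S[-1, -1] == 10.0

    def test_all_ones_5x5(self):
        S = integral_image(np.ones((5, 5)))
        ii, jj = np.mgrid[0:5, 0:5]
        np.testing.assert_array_equal(S[1:, 1:], (ii + 1) * (jj + 1))

    def test_window_sums_match_naive(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16)) * 100
        means = window_mean(img, 3)
        for i in range(16):
            for j in range(16):
                win = img[max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2]
                assert means[i, j] == pytest.approx(win.mean(), abs=1e-9)

    def test_non_finite_rejected(self):
        img = np.ones((4, 4))
        img[1, 1] = np.inf
        with pytest.raises(ValueError):
            integral_image(img)


class TestBradleyThreshold:
    def test_uniform_image_all_foreground(self):
        img = np.full((20, 20), 13.0)
        params = SegmentationParams(window_size=5, sensitivity=0.1)
        assert bradley_threshold(img, params).all()

    def test_matches_brute_force_on_random_image(self):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32)) * 1000
        params = SegmentationParams(window_size=9, sensitivity=0.15)
        expected = brute_force_bradley(img, 9, 0.15)
        np.testing.assert_array_equal(bradley_threshold(img, params), expected)

    def test_bright_square_on_dark_field(self):
        img = np.full((40, 40), 10.0)
        img[17:23, 17:23] = 200.0
        params = SegmentationParams(window_size=15, sensitivity=0.2)
        mask = bradley_threshold(img, params)
        expected = brute_force_bradley(img, 15, 0.2)
        np.testing.assert_array_equal(mask, expected)
        assert mask[18:22, 18:22].all()  # square interior
        # near the square the window mean is pulled up: a suppressed moat
        # isolates the object (dark-ring behavior of the mean rule)
        moat = np.zeros_like(mask)
        moat[15:25, 15:25] = True
        moat[17:23, 17:23] = False
        assert not mask[moat].any()
        # far from the square the window is uniform, so the strict rule
        # marks those pixels foreground (same as the uniform-image case)
        assert mask[0, 0]

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError, match="window"):
            bradley_threshold(
                np.ones((10, 10)), SegmentationParams(window_size=11, sensitivity=0.1)
            )

    @settings(max_examples=25, deadline=None)
    @given(
        # bounded dynamic range: exact agreement with the naive rule holds
        # up to float64 cancellation, which adversarial subnormals defeat
        img=hnp.arrays(
            np.float64,
            st.tuples(st.integers(8, 24), st.integers(8, 24)),
            elements=st.floats(0.125, 1000, allow_nan=False, width=32),
        ),
        w=st.sampled_from([3, 5, 7]),
        s=st.floats(0.01, 0.9),
    )
    def test_property_matches_brute_force(self, img, w, s):
        params = SegmentationParams(window_size=w, sensitivity=s)
        np.testing.assert_array_equal(
            bradley_threshold(img, params), brute_force_bradley(img, w, s)
        )

    def test_monotone_in_sensitivity(self):
        rng = np.random.default_rng(2)
        img = rng.random((48, 48)) * 500
        prev = None
        for s in (0.05, 0.1, 0.2, 0.4, 0.8):
            mask = bradley_threshold(img, SegmentationParams(window_size=9, sensitivity=s))
            if prev is not None:
                assert np.all(mask[prev])  # exact set inclusion
            prev = mask


class TestLabelComponents:
    def test_diagonal_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_components(mask, 8).max() == 1
        assert label_components(mask, 4).max() == 2

    def test_empty_mask(self):
        assert label_components(np.zeros((5, 5), dtype=bool)).max() == 0

    def test_raster_scan_order(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[4, 1] = True  # second in raster order
        mask[0, 5] = True  # first in raster order
        lab = label_components(mask)
        assert lab[0, 5] == 1
        assert lab[4, 1] == 2

    def test_synthetic_scene_components(self, clean_scene, default_config):
        from microquant.pipeline import run_pipeline

        seeds = SeedSet(clean_scene.seeds)
        result = run_pipeline(clean_scene.image, seeds, default_config, tune=True)
        # exactly the 20 planted cells survive the area filter + seed selection
        assert result.labels_selected.max() == 20


class TestFilterByArea:
    def test_identity_when_all_within_bounds(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:3, 1:3] = True
        mask[6:9, 6:9] = True
        lab = label_components(mask)
        np.testing.assert_array_equal(filter_by_area(lab, 1, 100), lab)

    def test_all_removed(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:3, 1:3] = True
        lab = label_components(mask)
        assert filter_by_area(lab, 100, 200).max() == 0

    def test_speckles_rejected(self, clean_scene):
        lab = clean_scene.truth_mask.astype(np.int32).copy()
        rng = np.random.default_rng(0)
        next_label = lab.max() + 1
        planted = 0
        while planted < 30:
            y, x = rng.integers(0, lab.shape[0]), rng.integers(0, lab.shape[1])
            if lab[max(y-1,0):y+2, max(x-1,0):x+2].sum() == 0:
                lab[y, x] = next_label
                next_label += 1
                planted += 1
        min_area = min(r.area_px for r in clean_scene.records) // 2
        out = filter_by_area(lab, min_area, 10**6)
        assert out.max() == 20

    def test_relabeling_is_compact_and_ordered(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[0, 0:4] = True     # area 4, first
        mask[5, 5] = True       # area 1, dropped
        mask[10, 2:8] = True    # area 6, second
        lab = label_components(mask)
        out = filter_by_area(lab, 2, 100)
        assert out[0, 0] == 1
        assert out[10, 2] == 2
        assert out[5, 5] == 0


class TestSelectBySeeds:
    def test_seed_on_background_is_missed(self):
        lab = np.zeros((10, 10), dtype=np.int32)
        lab[2:4, 2:4] = 1
        sel, det, mis = select_by_seeds(lab, SeedSet([(8, 8)]))
        assert det == []
        assert mis == [(8, 8)]
        assert sel.max() == 0

    def test_full_detection_rate(self, clean_scene):
        sel, det, mis = select_by_seeds(
            clean_scene.truth_mask.astype(np.int32), SeedSet(clean_scene.seeds)
        )
        assert len(det) == len(clean_scene.seeds)
        assert mis == []

    def test_merge_warning(self, caplog):
        lab = np.zeros((10, 10), dtype=np.int32)
        lab[2:8, 2:8] = 1
        with caplog.at_level(logging.WARNING, logger="microquant.segment"):
            sel, det, mis = select_by_seeds(lab, SeedSet([(3, 3), (6, 6)]))
        assert sel.max() == 1
        assert len(det) == 2
        assert any("MERGE" in r.message for r in caplog.records)

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            select_by_seeds(np.zeros((5, 5), dtype=np.int32), SeedSet(np.empty((0, 2))))

    def test_out_of_bounds_seed_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            select_by_seeds(np.zeros((5, 5), dtype=np.int32), SeedSet([(9, 1)]))


class TestTuner:
    def test_perfect_grid_point_found(self, clean_scene, default_config):
        from microquant import preprocess as pp

        img = pp.despeckle(clean_scene.image, 1.0)
        field = pp.estimate_background(
            img, pp.PreprocessParams(sigma_large=64.0, expected_cell_diameter=16.0)
        )
        corrected = pp.correct_background(img, field)
        report = tune_parameters(
            corrected, SeedSet(clean_scene.seeds),
            default_config["tune"]["window_sizes"],
            default_config["tune"]["sensitivities"],
        )
        assert report.best_rate == 1.0

    def test_degenerate_sensitivity_floods(self, clean_scene):
        report = tune_parameters(
            clean_scene.image, SeedSet(clean_scene.seeds), [15], [0.999],
            min_area=40, max_area=1500,
        )
        assert report.best_rate == 0.0

    def test_tie_break_larger_w_smaller_s(self):
        img = np.full((64, 64), 10.0)  # every grid point gives the same rate
        report = tune_parameters(
            img, SeedSet([(32, 32)]), [5, 9], [0.1, 0.3],
            min_area=0, max_area=10**6,
        )
        assert report.best_window == 9
        assert report.best_sensitivity == 0.1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_parameters(np.ones((8, 8)), SeedSet([(1, 1)]), [], [0.1])


def test_params_validation():
    with pytest.raises(ValueError):
        SegmentationParams(window_size=4)
    with pytest.raises(ValueError):
        SegmentationParams(sensitivity=1.5)
    with pytest.raises(ValueError):
        SegmentationParams(connectivity=6)
    with pytest.raises(ValueError):
        SegmentationParams(min_area=100, max_area=50)
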