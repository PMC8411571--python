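import math

import numpy as np
import pytest
from scipy import stats

from ecrap1 import synthetic_data as sd
from ecrap1.image_quant import (
    RoiPolygon,
    StripBatch,
    classify_pla_signals,
    compare_groups,
    quantify_roi_fraction,
    quantify_strip_intensity,
    rasterize_roi,
)


class TestRoiPolygon:
    def test_rect_helper_covers_expected_pixels(self):
        roi = RoiPolygon.from_rect(10, 10, 50, 50)
        mask = rasterize_roi(roi, (100, 100))
        assert mask.sum() == 2_500
        assert mask[10, 10] and mask[59, 59] and not mask[9, 10] and not mask[60, 60]

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            RoiPolygon(((0, 0), (10, 10)))
        with pytest.raises(ValueError):  # self-intersecting bow-tie
            RoiPolygon(((0, 0), (10, 10), (10, 0), (0, 10)))

    def test_roi_outside_image_rejected(self):
        roi = RoiPolygon.from_rect(90, 90, 20, 20)
        with pytest.raises(ValueError):
            rasterize_roi(roi, (100, 100))

    def test_triangle_area_matches_geometry(self):
        # right triangle, legs 60 px: rasterized pixel-center area ~ 1800
        roi = RoiPolygon(((0, 0), (60, 0), (0, 60)))
        area = rasterize_roi(roi, (80, 80)).sum()
        assert area == pytest.approx(1_800, abs=60)


class TestRoiFraction:
    def test_planted_fraction_exact(self):
        roi = RoiPolygon.from_rect(10, 10, 50, 50)
        spec = sd.SyntheticImageSpec(seed=3, shape=(100, 100), roi=roi, n_signal_px=300)
        fx = sd.gen_image(spec)
        q = quantify_roi_fraction(fx.image, roi, spec.threshold)
        assert (q.signal_px, q.roi_area_px) == (300, 2_500)
        assert q.value == pytest.approx(0.12)

    def test_uniform_below_threshold_is_zero(self):
        roi = RoiPolygon.from_rect(0, 0, 10, 10)
        q = quantify_roi_fraction(np.full((20, 20), 5.0), roi, threshold=128)
        assert q.value == 0.0

    def test_saturated_roi_is_one(self):
        roi = RoiPolygon.from_rect(0, 0, 10, 10)
        q = quantify_roi_fraction(np.full((20, 20), 200.0), roi, threshold=128)
        assert q.value == 1.0

    def test_invariant_to_pixels_outside_roi(self, rng):
        roi = RoiPolygon.from_rect(10, 10, 50, 50)
        spec = sd.SyntheticImageSpec(seed=4, shape=(100, 100), roi=roi, n_signal_px=123)
        fx = sd.gen_image(spec)
        scrambled = fx.image.copy()
        outside = ~fx.roi_mask
        scrambled[outside] = rng.permutation(scrambled[outside])
        scrambled[0, 0] = 255.0
        q1 = quantify_roi_fraction(fx.image, roi, spec.threshold)
        q2 = quantify_roi_fraction(scrambled, roi, spec.threshold)
        assert q1.value == q2.value

    def test_intensity_and_threshold_rescale_invariance(self):
        roi = RoiPolygon.from_rect(10, 10, 50, 50)
        spec = sd.SyntheticImageSpec(seed=5, shape=(100, 100), roi=roi, n_signal_px=77)
        fx = sd.gen_image(spec)
        q1 = quantify_roi_fraction(fx.image, roi, spec.threshold)
        q2 = quantify_roi_fraction(fx.image * 2.0, roi, spec.threshold * 2.0)
        assert q1.value == q2.value


class TestStripIntensity:
    def test_constant_strip_mean(self):
        image = np.full((50, 50), 40.0)
        assert quantify_strip_intensity(image, (10, 10, 20, 20)).value == 40.0

    def test_half_and_half_mean(self):
        image = np.zeros((10, 20))
        image[:, 10:] = 100.0
        assert quantify_strip_intensity(image, (0, 0, 10, 20)).value == 50.0

    def test_planted_noisy_mean_recovered_within_sem(self):
        spec = sd.SyntheticImageSpec(
            seed=6, shape=(64, 64),
            strip_rects=[(10, 10, 20, 40)], strip_means=[80.0], strip_sd=5.0,
        )
        fx = sd.gen_image(spec)
        rect, planted, realized = fx.strip_truth[0]
        q = quantify_strip_intensity(fx.image, rect)
        assert q.value == pytest.approx(realized, abs=1e-9)  # exact vs realized
        sem = 5.0 / math.sqrt(20 * 40)
        assert q.value == pytest.approx(planted, abs=4 * sem)

    def test_batch_enforces_fixed_selection_size(self):
        batch = StripBatch()
        image = np.zeros((50, 50))
        batch.measure(image, (0, 0, 10, 10))
        with pytest.raises(ValueError, match="fixed size"):
            batch.measure(image, (0, 0, 10, 12))

    def test_strip_doubles_when_intensity_doubles(self):
        image = np.full((20, 20), 40.0)
        rect = (0, 0, 10, 10)
        assert (
            quantify_strip_intensity(image * 2, rect).value
            == 2 * quantify_strip_intensity(image, rect).value
        )

    def test_rect_outside_image_rejected(self):
        with pytest.raises(ValueError):
            quantify_strip_intensity(np.zeros((10, 10)), (5, 5, 10, 10))


class TestCompareGroups:
    def test_identical_groups(self):
        r = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_matches_scipy_on_ordinary_data(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        r = compare_groups(a, b)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert (r.t, r.p) == (pytest.approx(t), pytest.approx(p))
        assert r.sem_a == pytest.approx(np.std(a, ddof=1) / math.sqrt(12))

    def test_zero_variance_shift_is_degenerate_not_crash(self):
        r = compare_groups([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert not r.degenerate  # ordinary case: nonzero within-group sd
        r = compare_groups([5.0, 5.0], [7.0, 7.0])
        assert r.degenerate and r.t == -math.inf and r.p == 0.0
        r = compare_groups([5.0, 5.0], [5.0, 5.0])
        assert r.degenerate and r.t == 0.0 and r.p == 1.0

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestPlaClassification:
    def test_wild_type_partition(self):
        spec = sd.SyntheticImageSpec(seed=7, shape=(128, 128), pla_partition=(36, 95))
        fx = sd.gen_image(spec)
        r = classify_pla_signals(fx.pla_centroids, fx.nuclear_mask)
        assert (r.n_total, r.n_nuclear, r.n_cytoplasmic) == (131, 36, 95)
        assert r.pct_cytoplasmic == pytest.approx(72.5, abs=0.05)

    def test_all_nuclear_gives_zero_pct(self):
        mask = np.ones((10, 10), dtype=bool)
        r = classify_pla_signals([(2.0, 2.0), (5.0, 5.0)], mask)
        assert r.pct_cytoplasmic == 0.0

    def test_totals_conserved(self):
        spec = sd.SyntheticImageSpec(seed=8, shape=(96, 96), pla_partition=(40, 21))
        fx = sd.gen_image(spec)
        r = classify_pla_signals(fx.pla_centroids, fx.nuclear_mask)
        assert r.n_total == r.n_nuclear + r.n_cytoplasmic == 61

    def test_empty_centroids_rejected(self):
        with pytest.raises(ValueError):
            classify_pla_signals([], np.zeros((5, 5), dtype=bool))

    def test_centroid_outside_image_rejected(self):
        with pytest.raises(ValueError):
            classify_pla_signals([(99.0, 1.0)], np.zeros((5, 5), dtype=bool))
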