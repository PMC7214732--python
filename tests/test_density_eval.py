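import numpy as np
import pytest

from veinseg import (
    SegmentationLevel,
    accuracy,
    mask_to_veinmap,
    pixel_metrics,
    skeleton_length_px,
    vein_density,
)

from conftest import make_image


class TestSkeletonLength:
    def test_horizontal_line(self):
        s = np.zeros((5, 10), bool)
        s[2, :] = True
        assert skeleton_length_px(s) == pytest.approx(9.0)

    def test_diagonal_line(self):
        s = np.eye(8, dtype=bool)
        assert skeleton_length_px(s) == pytest.approx(7 * np.sqrt(2))

    def test_corner_does_not_double_count_diagonal(self):
        s = np.zeros((3, 3), bool)
        s[0, 0] = s[0, 1] = s[1, 1] = True
        assert skeleton_length_px(s) == pytest.approx(2.0)

    def test_isolated_pixel_contributes_nothing(self):
        s = np.zeros((3, 3), bool)
        s[1, 1] = True
        assert skeleton_length_px(s) == 0.0


class TestVeinDensity:
    def test_full_width_line_reference_field(self):
        w, h = 1024, 766
        mask = np.zeros((h, w), bool)
        mask[383, :] = True
        img = make_image(np.zeros((h, w)), field=(2.2013, 1.6468))
        vm = mask_to_veinmap(mask, img, skeleton=mask, tip_correction=False)
        px = img.pixel_size_mm
        # (W-1) unit steps; area = W*H*px^2 per the calibration contract
        expected = (2.2013 - px) / (w * h * px**2)
        assert vm.density_mm_per_mm2 == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.607, abs=2e-3)

    def test_empty_mask_density_zero(self):
        img = make_image(np.zeros((10, 10)))
        vm = mask_to_veinmap(np.zeros((10, 10), bool), img)
        assert vm.density_mm_per_mm2 == 0.0
        assert vm.total_length_mm == 0.0

    def test_diagonal_line_length(self):
        n = 200
        mask = np.eye(n, dtype=bool)
        img = make_image(np.zeros((n, n)), field=(1.0, 1.0))
        vm = mask_to_veinmap(mask, img, skeleton=mask, tip_correction=False)
        assert vm.total_length_mm == pytest.approx((n - 1) * np.sqrt(2) / n, rel=1e-9)

    def test_from_level_and_rotation_invariance(self):
        mask = np.zeros((40, 60), bool)
        mask[10:13, 5:55] = True
        labels = np.where(mask, 0, 1).astype(np.int32)
        img = make_image(np.zeros((40, 60)), field=(1.2, 0.8))
        level = SegmentationLevel(labels, img)
        vm = vein_density(level, [0], img)
        # same scene rotated 90 degrees (field swapped to keep pixels square)
        img2 = make_image(np.zeros((60, 40)), field=(0.8, 1.2))
        level2 = SegmentationLevel(np.rot90(labels).copy(), img2)
        vm2 = vein_density(level2, [0], img2)
        assert vm.density_mm_per_mm2 == pytest.approx(vm2.density_mm_per_mm2, rel=1e-9)

    def test_resolution_doubling_stable(self):
        # the same physical scene rendered at 1x and 2x sampling
        from scipy import ndimage
        from skimage.draw import line

        def scene(scale):
            h, w = 100 * scale, 150 * scale
            mask = np.zeros((h, w), bool)
            rr, cc = line(20 * scale, 10 * scale, 80 * scale, 140 * scale)
            mask[rr, cc] = True
            mask = ndimage.binary_dilation(mask, iterations=scale)
            img = make_image(np.zeros((h, w)), field=(1.5, 1.0))
            return mask_to_veinmap(mask, img).density_mm_per_mm2

        d1, d2 = scene(1), scene(2)
        assert abs(d2 - d1) / d1 < 0.05

    def test_skeleton_subset_of_mask(self):
        mask = np.zeros((30, 30), bool)
        mask[5:25, 10:16] = True
        vm = mask_to_veinmap(mask, make_image(np.zeros((30, 30))))
        assert not (vm.skeleton & ~vm.vein_mask).any()


class TestAccuracy:
    def test_identity_is_exact_hundred(self):
        rep = accuracy([1.3, 0.9, 2.2], [1.3, 0.9, 2.2])
        assert rep.R == 0.0
        assert rep.P_prime == 100.0

    def test_hand_example(self):
        rep = accuracy([1.2, 1.0], [1.0, 1.0])
        assert rep.R == pytest.approx(0.1)
        assert rep.P_bar1 == pytest.approx(1.1)
        assert rep.P_prime == pytest.approx((1.1 - 0.1) / 1.1 * 100)

    def test_signed_errors_cancel(self):
        # documented behaviour of the signed-mean-error formula
        rep = accuracy([1.0, 1.0], [0.9, 1.1])
        assert rep.R == pytest.approx(0.0, abs=1e-15)
        assert rep.P_prime == pytest.approx(100.0)

    def test_rmse_variant(self):
        rep = accuracy([1.0, 1.0], [0.9, 1.1], rmse=True)
        assert rep.R == pytest.approx(0.1)

    def test_brute_force_fidelity(self, rng):
        p1 = rng.uniform(0.5, 3.0, 50)
        p0 = p1 + rng.normal(0, 0.1, 50)
        rep = accuracy(p1, p0)
        r = sum(a - b for a, b in zip(p1, p0)) / 50
        pbar = sum(p1) / 50
        assert rep.R == pytest.approx(r, abs=1e-12)
        assert rep.P_prime == pytest.approx((pbar - r) / pbar * 100, abs=1e-12)

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            accuracy([], [])
        with pytest.raises(ValueError):
            accuracy([1.0], [1.0, 2.0])
        with pytest.raises(ZeroDivisionError):
            accuracy([1.0, -1.0], [0.5, 0.5])


class TestPixelMetrics:
    def test_perfect_prediction(self):
        t = np.zeros((10, 10), bool)
        t[4, :] = True
        m = pixel_metrics(t, t)
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_empty_prediction_convention(self):
        t = np.zeros((5, 5), bool)
        t[2, 2] = True
        m = pixel_metrics(np.zeros((5, 5), bool), t)
        assert m.precision == 1.0
        assert m.recall == 0.0

    def test_shifted_by_one_within_tolerance(self):
        t = np.zeros((10, 20), bool)
        t[5, 2:18] = True
        p = np.zeros((10, 20), bool)
        p[6, 2:18] = True
        m = pixel_metrics(p, t, tolerance_px=2)
        assert m.f1 == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pixel_metrics(np.zeros((2, 2), bool), np.zeros((3, 3), bool))
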