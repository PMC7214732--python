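import numpy as np
import pytest

from veinseg import (
    RuleSet,
    SceneConfig,
    generate,
    linear_stretch,
    perturb_with_occlusions,
    skeleton_length_px,
)
from veinseg.synth import gap_closure


@pytest.fixture(scope="module")
def clean_scene():
    return generate(SceneConfig(seed=7))


@pytest.fixture(scope="module")
def gap_scene():
    return generate(SceneConfig(seed=7, n_gaps=4))


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate(SceneConfig(seed=3, n_gaps=2))
        b = generate(SceneConfig(seed=3, n_gaps=2))
        assert (a.image.pixels == b.image.pixels).all()
        assert (a.truth_mask == b.truth_mask).all()
        assert a.truth_length_mm == b.truth_length_mm

    def test_different_seeds_differ(self):
        a = generate(SceneConfig(seed=3))
        b = generate(SceneConfig(seed=4))
        assert (a.image.pixels != b.image.pixels).any()


class TestGroundTruth:
    def test_no_gaps_rendered_equals_truth(self, clean_scene):
        assert (clean_scene.rendered_mask == clean_scene.truth_mask).all()
        assert clean_scene.gap_list == ()

    def test_truth_length_matches_skeleton_step_sum(self, clean_scene):
        px = clean_scene.image.pixel_size_mm
        assert clean_scene.truth_length_mm == pytest.approx(
            skeleton_length_px(clean_scene.truth_skeleton) * px, abs=1e-9
        )

    def test_skeleton_subset_of_mask(self, clean_scene):
        assert not (clean_scene.truth_skeleton & ~clean_scene.truth_mask).any()

    def test_homothety_scales_length_linearly(self):
        a = generate(SceneConfig(seed=5))
        b = generate(SceneConfig(seed=5, field_mm=(4.4026, 3.2936)))
        assert b.truth_length_mm == pytest.approx(2 * a.truth_length_mm, rel=1e-9)

    def test_parallel_mode_density(self):
        cfg = SceneConfig(seed=2, venation="parallel", n_parallel=5)
        sc = generate(cfg)
        w_mm, h_mm = cfg.field_mm
        expected = 5 * w_mm / (w_mm * h_mm)
        assert sc.truth_density_mm_per_mm2 == pytest.approx(expected, rel=0.03)


class TestGeneratorContract:
    def test_rule_separation_on_classification_scale(self, clean_scene):
        """>=99% of vein px satisfy and >=99% of background px violate the
        default brightness/red bounds after the contrast stretch."""
        rules = RuleSet()
        st = linear_stretch(clean_scene.image).pixels.astype(float)
        bright = st.mean(axis=2)
        red = st[:, :, 0]
        ok = (
            (bright >= rules.brightness_min)
            & (bright <= rules.brightness_max)
            & (red >= rules.red_min)
        )
        vein = clean_scene.rendered_mask
        assert ok[vein].mean() >= 0.99
        assert (~ok[~vein]).mean() >= 0.99

    def test_raw_scale_separation_too(self, clean_scene):
        raw = clean_scene.image.pixels.astype(float)
        bright = raw.mean(axis=2)
        red = raw[:, :, 0]
        ok = (bright >= 230) & (bright <= 280) & (red >= 180)
        assert ok[clean_scene.rendered_mask].mean() >= 0.99
        assert (~ok[~clean_scene.truth_mask]).mean() >= 0.99


class TestOcclusions:
    def test_gaps_recorded_and_cut(self, gap_scene):
        assert len(gap_scene.gap_list) == 4
        for g in gap_scene.gap_list:
            # removed pixels are truth but not rendered
            rr, cc = g.cut_pixels.T
            assert gap_scene.truth_mask[rr, cc].all()
            assert not gap_scene.rendered_mask[rr, cc].any()
            # anchors survive on both flanks
            assert gap_scene.rendered_mask[g.anchor_a]
            assert gap_scene.rendered_mask[g.anchor_b]

    def test_gaps_disconnect_network(self, gap_scene):
        from scipy import ndimage

        four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
        comp, _ = ndimage.label(gap_scene.rendered_mask, structure=four)
        for g in gap_scene.gap_list:
            assert comp[g.anchor_a] != comp[g.anchor_b]

    def test_pixel_accounting(self, gap_scene):
        removed = gap_scene.truth_mask.sum() - gap_scene.rendered_mask.sum()
        per_gap = [len(g.cut_pixels) for g in gap_scene.gap_list]
        assert removed == sum(per_gap)
        for g, npx in zip(gap_scene.gap_list, per_gap):
            width = gap_scene.strokes[g.stroke_index].width_px
            assert npx >= g.length_px * width * 0.5

    def test_perturb_zero_gaps_is_identity(self, clean_scene):
        assert perturb_with_occlusions(clean_scene, 0, 4) is clean_scene

    def test_perturb_adds_gaps_and_keeps_truth(self, clean_scene):
        sc = perturb_with_occlusions(clean_scene, 2, (2, 4))
        assert len(sc.gap_list) == 2
        assert (sc.truth_mask == clean_scene.truth_mask).all()
        assert sc.rendered_mask.sum() < clean_scene.rendered_mask.sum()
        # deterministic
        sc2 = perturb_with_occlusions(clean_scene, 2, (2, 4))
        assert (sc.image.pixels == sc2.image.pixels).all()

    def test_gap_closure_audit(self, gap_scene):
        # the full truth closes every gap; the rendered mask closes none
        assert all(gap_closure(gap_scene.truth_mask, gap_scene))
        assert not any(gap_closure(gap_scene.rendered_mask, gap_scene))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SceneConfig(venation="circular")
    with pytest.raises(ValueError):
        SceneConfig(size_px=(8, 8))
    with pytest.raises(ValueError):
        SceneConfig(field_mm=(0.0, 1.0))
    with pytest.raises(ValueError):
        SceneConfig(gap_len_px=(5, 2))
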