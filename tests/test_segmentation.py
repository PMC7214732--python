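import numpy as np
import pytest

from veinseg import (
    SegmentationParams,
    SegmentationLevel,
    chessboard_segment,
    merge_cost,
    merge_objects,
    multiresolution_segment,
)

from conftest import brute_merge_cost, brute_object_stats, make_image


def level_from_labels(labels, pixels):
    return SegmentationLevel(np.asarray(labels, dtype=np.int32), make_image(pixels))


class TestMergeCost:
    def test_constant_objects_zero_color_cost(self):
        labels = [[0, 1]]
        level = level_from_labels(labels, [[5, 5]])
        p = SegmentationParams(scale=10, shape_weight=0.0)
        assert merge_cost(level.object(0), level.object(1), p) == pytest.approx(0.0)

    def test_two_pixel_color_cost_is_twice_population_sd(self):
        level = level_from_labels([[0, 1]], [[10, 20]])
        p = SegmentationParams(scale=10, shape_weight=0.0, band_weights=(1, 0, 0))
        # merged object {10, 20}: population SD 5, n_ab = 2
        assert merge_cost(level.object(0), level.object(1), p) == pytest.approx(10.0)

    def test_compactness_term_for_unit_square_pair(self):
        level = level_from_labels([[0, 1]], [[0, 0]])
        p = SegmentationParams(scale=10, shape_weight=1.0, compactness_weight=1.0)
        expected = 2 * (6 / np.sqrt(2)) - 2 * 4.0  # 8.485... - 8
        assert merge_cost(level.object(0), level.object(1), p) == pytest.approx(
            expected
        )

    def test_non_adjacent_pair_rejected(self):
        level = level_from_labels([[0, 1, 2]], [[0, 0, 0]])
        p = SegmentationParams()
        with pytest.raises(ValueError):
            merge_cost(level.object(0), level.object(2), p)

    def test_matches_brute_force_on_random_partitions(self, rng):
        for _ in range(5):
            pixels = rng.integers(0, 256, (8, 8, 3)).astype(np.int32)
            labels = rng.integers(0, 4, (8, 8)).astype(np.int32)
            labels[:4, :] = np.where(labels[:4, :] > 1, 0, labels[:4, :])
            level = level_from_labels(labels, pixels)
            u, v, _ = level.adjacency()
            p = SegmentationParams(scale=50, shape_weight=0.4, compactness_weight=0.6)
            for a, b in zip(u[:6], v[:6]):
                got = merge_cost(level.object(int(a)), level.object(int(b)), p)
                want = brute_merge_cost(labels, pixels, int(a), int(b), p)
                assert got == pytest.approx(want, rel=1e-9, abs=1e-9)


class TestMultiresolutionSegment:
    def test_constant_image_single_object(self):
        img = make_image(np.full((12, 16), 40))
        level = multiresolution_segment(img, SegmentationParams(scale=5, shape_weight=0.0))
        assert level.n_objects == 1

    def test_two_halves_stay_separate_when_gap_exceeds_scale(self):
        # Final cross-boundary cost for two constant 8x8 halves with gap G:
        # dh_color = n_ab * sd_ab = 128 * G/2 (population SD of a balanced
        # two-valued set is G/2).  scale^2 = 100 < 128 * 25 with G = 50.
        arr = np.zeros((8, 16), dtype=np.int32)
        arr[:, 8:] = 50
        level = multiresolution_segment(
            make_image(arr), SegmentationParams(scale=10, shape_weight=0.0)
        )
        assert level.n_objects == 2
        assert len(np.unique(level.labels[:, :8])) == 1
        assert len(np.unique(level.labels[:, 8:])) == 1

    def test_tiny_scale_keeps_every_pixel_separate(self, rng):
        arr = rng.integers(0, 255, (6, 7)).astype(np.int32)
        level = multiresolution_segment(
            make_image(arr), SegmentationParams(scale=1e-6)
        )
        assert level.n_objects == 42

    def test_partition_invariant(self, rng):
        arr = rng.integers(0, 256, (16, 16, 3)).astype(np.int32)
        level = multiresolution_segment(make_image(arr), SegmentationParams(scale=20))
        assert level.labels.min() == 0
        assert level.table.n.sum() == 16 * 16

    def test_mask_confines_segmentation(self, rng):
        arr = rng.integers(0, 256, (10, 10)).astype(np.int32)
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:7, 3:9] = True
        level = multiresolution_segment(
            make_image(arr), SegmentationParams(scale=15), mask=mask
        )
        assert (level.labels[~mask] == -1).all()
        assert (level.labels[mask] >= 0).all()

    def test_deterministic(self, rng):
        arr = rng.integers(0, 256, (20, 20, 3)).astype(np.int32)
        p = SegmentationParams(scale=15)
        l1 = multiresolution_segment(make_image(arr), p)
        l2 = multiresolution_segment(make_image(arr), p)
        assert (l1.labels == l2.labels).all()

    def test_object_count_non_increasing_in_scale(self, rng):
        arr = (
            rng.integers(0, 40, (24, 24, 3))
            + np.kron(rng.integers(0, 8, (4, 4)) * 25, np.ones((6, 6)))[:, :, None]
        ).astype(np.int32)
        img = make_image(arr)
        counts = [
            multiresolution_segment(img, SegmentationParams(scale=s)).n_objects
            for s in (2, 5, 10, 20, 50, 100)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_accepted_merges_below_and_survivors_above_threshold(self, rng):
        """Oracle audit on a small random image (full version in acceptance)."""
        from test_acceptance import audit_segmentation

        arr = rng.integers(0, 256, (16, 16, 3)).astype(np.int32)
        audit_segmentation(make_image(arr), SegmentationParams(scale=8))


class TestIncrementalStatistics:
    def test_stats_match_brute_force(self, rng):
        arr = rng.integers(0, 256, (14, 14, 3)).astype(np.int32)
        level = multiresolution_segment(make_image(arr), SegmentationParams(scale=12))
        t = level.table
        for oid in range(level.n_objects):
            b = brute_object_stats(level.labels, arr, oid)
            assert t.n[oid] == b["n"]
            np.testing.assert_allclose(t.band_mean[oid], b["mean"], rtol=1e-9)
            np.testing.assert_allclose(t.band_sd[oid], b["sd"], rtol=1e-6, atol=1e-9)
            assert t.border_length[oid] == b["border"]
            assert tuple(t.bbox[oid]) == b["bbox"]
            assert t.var_r[oid] == pytest.approx(b["var_r"], abs=1e-9)
            assert t.var_c[oid] == pytest.approx(b["var_c"], abs=1e-9)


class TestChessboard:
    def test_tile_one_pixelises(self):
        level = level_from_labels(np.zeros((4, 4), int), np.zeros((4, 4)))
        out = chessboard_segment(level, [0], tile=1)
        assert out.n_objects == 16

    def test_exact_tiling(self):
        level = level_from_labels(np.zeros((4, 4), int), np.zeros((4, 4)))
        assert chessboard_segment(level, [0], tile=2).n_objects == 4

    def test_partial_edge_tiles_kept(self):
        level = level_from_labels(np.zeros((5, 5), int), np.zeros((5, 5)))
        assert chessboard_segment(level, [0], tile=2).n_objects == 9

    def test_unlisted_objects_untouched(self):
        labels = np.zeros((4, 8), int)
        labels[:, 4:] = 1
        level = level_from_labels(labels, np.zeros((4, 8)))
        out = chessboard_segment(level, [0], tile=1)
        assert out.n_objects == 17  # 16 pixels + untouched object 1
        right = out.labels[:, 4:]
        assert len(np.unique(right)) == 1

    def test_unknown_id_rejected(self):
        level = level_from_labels(np.zeros((4, 4), int), np.zeros((4, 4)))
        with pytest.raises(KeyError):
            chessboard_segment(level, [3], tile=2)


class TestMergeObjects:
    def test_adjacent_merge_conserves_pixels(self):
        labels = np.array([[0, 0, 1, 1]])
        level = level_from_labels(labels, [[1, 2, 3, 4]])
        out = merge_objects(level, [0, 1])
        assert out.n_objects == 1
        assert out.table.n[0] == 4

    def test_non_touching_objects_stay_separate(self):
        labels = np.array([[0, 1, 2]])
        level = level_from_labels(labels, [[1, 2, 3]])
        out = merge_objects(level, [0, 2])
        assert out.n_objects == 3

    def test_merged_mean_is_pixel_weighted(self):
        labels = np.array([[0, 0, 0, 1]])
        level = level_from_labels(labels, [[10, 10, 10, 50]])
        out = merge_objects(level, [0, 1])
        merged_id = out.labels[0, 0]
        assert out.table.band_mean[merged_id][0] == pytest.approx(20.0)

    def test_empty_id_set_rejected(self):
        level = level_from_labels(np.zeros((2, 2), int), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            merge_objects(level, [])
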