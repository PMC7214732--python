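import numpy as np
import pytest
from scipy import ndimage

from veinseg import (
    ReconnectionConfig,
    SegmentationLevel,
    grow_gaps,
    reconnect,
    straighten,
)
from veinseg import density as density_feature

from conftest import make_image

FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)


def bar_level(mask, bright=250, dark=80):
    """Level with object 0 = mask (bright) and object 1 = the rest."""
    labels = np.where(mask, 0, 1).astype(np.int32)
    pix = np.where(mask[:, :, None], bright, dark).astype(np.int32)
    pix = np.repeat(pix, 3, axis=2) if pix.shape[2] == 1 else pix
    return SegmentationLevel(labels, make_image(pix))


class TestSchedules:
    def test_default_ladder_has_26_passes(self):
        cfg = ReconnectionConfig()
        scales = cfg.schedule()
        assert len(scales) == 26
        assert scales[0] == pytest.approx(150.0)
        assert scales[-1] == pytest.approx(150 * 0.9**25)
        assert scales[-1] > 10 >= scales[-1] * 0.9

    def test_straighten_executes_full_schedule(self):
        mask = np.zeros((20, 40), bool)
        mask[9:12, 5:35] = True
        level = bar_level(mask)
        res = straighten(level, [0])
        assert res.n_passes == 26

    def test_grow_runs_exactly_the_configured_cycles(self):
        mask = np.zeros((20, 40), bool)
        mask[9:12, 5:18] = True
        mask[9:12, 22:35] = True
        level = bar_level(mask)
        sr = straighten(level, [0])
        gr = grow_gaps(sr.level, ReconnectionConfig(), seed_ids=sr.temp02_ids)
        assert gr.cycles_run == 8
        assert len(gr.added_per_cycle) == 8

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ReconnectionConfig(fg_decay=1.5)
        with pytest.raises(ValueError):
            ReconnectionConfig(fg_stop=200.0)
        with pytest.raises(ValueError):
            ReconnectionConfig(growth_cycles=0)


class TestStraighten:
    def test_straight_bar_single_piece_covering_input(self):
        mask = np.zeros((20, 60), bool)
        mask[9:12, 5:55] = True
        level = bar_level(mask)
        res = straighten(level, [0])
        covered = np.isin(res.level.labels, res.temp02_ids)
        assert (covered == mask).all()

    def test_every_piece_is_elongated(self):
        # L-shaped vein: all resulting pieces must satisfy the density bound
        mask = np.zeros((60, 60), bool)
        mask[28:31, 5:55] = True
        mask[5:31, 28:31] = True
        level = bar_level(mask)
        res = straighten(level, [0])
        t = res.level.table
        for oid in res.temp02_ids:
            obj = res.level.object(int(oid))
            assert density_feature(obj) < 2.0
        assert t.n[res.temp02_ids].sum() == mask.sum()

    def test_empty_vein_set_is_noop(self):
        mask = np.zeros((10, 10), bool)
        level = bar_level(mask)
        res = straighten(level, [])
        assert res.temp02_ids.size == 0


class TestGrow:
    def test_collinear_gap_is_bridged(self):
        mask = np.zeros((20, 40), bool)
        mask[9:12, 2:18] = True
        mask[9:12, 21:38] = True  # 3 px gap
        level = bar_level(mask)
        res = reconnect(level, [0])
        out = res.vein_mask()
        comp, n = ndimage.label(out, structure=FOUR)
        assert n == 1
        assert (out & mask == mask).all()  # superset of input

    def test_parallel_offset_bars_stay_separate(self):
        mask = np.zeros((60, 60), bool)
        mask[9:12, 2:28] = True
        mask[40:43, 32:58] = True  # far apart, not collinear
        level = bar_level(mask)
        res = reconnect(level, [0])
        comp, n = ndimage.label(res.vein_mask(), structure=FOUR)
        assert n == 2

    def test_no_seeds_is_noop(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 2:8] = True
        level = bar_level(mask)
        gr = grow_gaps(level, ReconnectionConfig(), seed_ids=np.array([], int))
        assert gr.grown_mask.sum() == 0

    def test_bridge_stays_in_bar_corridor(self):
        mask = np.zeros((30, 60), bool)
        mask[14:17, 2:25] = True
        mask[14:17, 30:58] = True  # 5 px gap
        level = bar_level(mask)
        res = reconnect(level, [0])
        grown = res.grow.grown_mask
        assert grown.any()
        corridor = np.zeros((30, 60), bool)
        corridor[12:19, :] = True  # bar rows +-2
        assert not (grown & ~corridor).any()

    def test_growth_monotone_and_rolled_back_tips_removed(self):
        mask = np.zeros((20, 40), bool)
        mask[9:12, 10:30] = True  # free bar: nothing to splice
        level = bar_level(mask)
        res = reconnect(level, [0])
        assert (res.vein_mask() == mask).all()  # all exploratory growth rolled back


class TestReconnect:
    def test_empty_classification_empty_output(self):
        mask = np.zeros((10, 10), bool)
        level = bar_level(mask)
        res = reconnect(level, [])
        assert res.vein_ids.size == 0
        assert not res.vein_mask().any()

    def test_connected_network_changes_little(self):
        mask = np.zeros((40, 80), bool)
        mask[19:22, 5:75] = True
        mask[5:20, 39:42] = True
        level = bar_level(mask)
        res = reconnect(level, [0])
        out = res.vein_mask()
        assert (out & mask == mask).all()
        extra = out.sum() - mask.sum()
        assert extra <= 0.01 * mask.sum()
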