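"""Circulating-growth reconnection of interrupted veins.

Trichomes and other occlusions interrupt the rendered vein network, so the
classified vein objects can be broken into disconnected fragments.  The
reconnection stage splices them back together in two steps:

1. **Straightening** — the vein pixels are decomposed into near-straight
   segments by re-segmenting them with a decreasing scale ladder
   (``fg01 = 150``, multiplied by 0.9 per pass while above 10, i.e. 26
   passes by default) using shape weight 0.7 and compactness weight 0.9;
   every object whose density feature falls below 2 is frozen as a
   *straight segment* and leaves the loop, and leftover pixels are frozen
   at loop exit.  Straight segments carry a well-defined principal
   direction, which is what makes directional growth possible.

2. **Growth** — the background around the segments is treated as a pool of
   single-pixel candidates (chessboard pixelisation of the merged
   background).  For a fixed number of cycles (8 by default), each segment
   fuses the adjacent background pixels that increase its principal length,
   i.e. the TL - SL > 0 length-fitting rule with target weight 1, seed
   weight -1 and candidate weight 0.  The lengths are evaluated on the
   *local end* of the segment — its pixels within a square window (radius
   ``window_radius``) around the candidate — because after straightening a
   segment may still be a whole branched fragment whose global axis says
   nothing about the direction of a particular interrupted end.  Lateral
   candidates shorten or preserve the local principal length and are
   rejected (the trivial sqrt(n) area inflation is removed and a small
   noise margin applied), so each free end advances a ring or two per
   cycle along its own axis — across occlusion gaps — and stops against
   other vein pixels.
   Segments that become adjacent are merged for output.  After the last
   cycle, growth that did not splice anything is rolled back: a grown pixel
   is kept only if it lies on a shortest path (through grown pixels)
   between two distinct pre-growth vein components.  Free vein tips
   therefore end where they ended before growth, and every closed gap keeps
   a tight bridge instead of the whole exploratory front.

The output vein pixel set always contains the input vein pixel set.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from . import features
from .knowledge_base import ClassMap
from .segmentation import (
    FOUR_CONNECTED,
    SegmentationLevel,
    SegmentationParams,
    multiresolution_segment,
)


@dataclasses.dataclass(frozen=True)
class ReconnectionConfig:
    """Parameters of the straightening ladder and the growth cycles."""

    fg01_init: float = 150.0
    fg_decay: float = 0.9
    fg_stop: float = 10.0
    straight_shape_weight: float = 0.7
    straight_compactness_weight: float = 0.9
    straightness_density_max: float = 2.0
    growth_cycles: int = 8
    growth_cap_rings: float = 2.0
    window_radius: int = 12
    max_bridge_px: int = 14
    min_elongation_gain: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.fg_decay < 1.0:
            raise ValueError("fg_decay must be in (0, 1)")
        if self.fg_stop >= self.fg01_init:
            raise ValueError("fg_stop must be below fg01_init")
        if self.growth_cycles < 1:
            raise ValueError("growth_cycles must be >= 1")

    def schedule(self) -> list[float]:
        """The scale values of the straightening passes (fg01 * decay^k > stop)."""
        scales = []
        fg = self.fg01_init
        while fg > self.fg_stop:
            scales.append(fg)
            fg *= self.fg_decay
        return scales


@dataclasses.dataclass
class StraightenResult:
    level: SegmentationLevel
    temp02_ids: np.ndarray
    n_passes: int
    scales: list[float]


@dataclasses.dataclass
class GrowResult:
    level: SegmentationLevel
    vein_ids: np.ndarray
    grown_mask: np.ndarray
    cycles_run: int
    added_per_cycle: list[int]
    pruned_px: int


@dataclasses.dataclass
class ReconnectResult:
    level: SegmentationLevel
    vein_ids: np.ndarray
    straighten: StraightenResult | None
    grow: GrowResult | None

    def vein_mask(self) -> np.ndarray:
        if self.vein_ids.size == 0:
            return np.zeros(self.level.labels.shape, dtype=bool)
        return np.isin(self.level.labels, self.vein_ids)


# ---------------------------------------------------------------------------
# Straightening
# ---------------------------------------------------------------------------

def straighten(
    level: SegmentationLevel,
    vein_ids: Sequence[int] | np.ndarray,
    cfg: ReconnectionConfig | None = None,
) -> StraightenResult:
    """Decompose the vein objects into straight segments (temp02).

    Runs the full decreasing-scale schedule; every vein pixel ends up in
    exactly one temp02 object.  Non-vein objects are untouched.
    """
    cfg = cfg or ReconnectionConfig()
    ids = np.asarray(list(vein_ids), dtype=np.int64)
    img = level.image
    h, w = level.labels.shape
    vein_mask = (
        np.isin(level.labels, ids) if ids.size else np.zeros((h, w), dtype=bool)
    )
    piece = np.full((h, w), -1, dtype=np.int64)
    next_piece = 0
    remaining = vein_mask.copy()
    scales = cfg.schedule()

    for scale in scales:
        if not remaining.any():
            continue
        params = SegmentationParams(
            scale=scale,
            shape_weight=cfg.straight_shape_weight,
            compactness_weight=cfg.straight_compactness_weight,
        )
        sub = multiresolution_segment(img, params, mask=remaining)
        t = sub.table
        dens = features._density_arrays(t.n.astype(float), t.var_r, t.var_c)
        frozen_ids = np.flatnonzero(dens < cfg.straightness_density_max)
        if frozen_ids.size == 0:
            continue
        remap = np.full(t.n_objects, -1, dtype=np.int64)
        remap[frozen_ids] = next_piece + np.arange(frozen_ids.size)
        sel = np.isin(sub.labels, frozen_ids)
        piece[sel] = remap[sub.labels[sel]]
        next_piece += frozen_ids.size
        remaining &= ~sel

    if remaining.any():  # leftover becomes temp02 by connected component
        comp, ncomp = ndimage.label(remaining, structure=FOUR_CONNECTED)
        piece[remaining] = next_piece + comp[remaining] - 1
        next_piece += ncomp

    # Rebuild the level: non-vein objects keep their partition, vein pixels
    # take the piece partition; ids are compacted.
    new = level.labels.astype(np.int64).copy()
    base = level.n_objects
    new[vein_mask] = base + piece[vein_mask]
    flat = new.ravel()
    inside = flat >= 0
    _, compact = np.unique(flat[inside], return_inverse=True)
    out = np.full(flat.shape, -1, dtype=np.int32)
    out[inside] = compact.astype(np.int32)
    out = out.reshape(h, w)
    new_level = SegmentationLevel(out, img)
    temp02_ids = np.unique(out[vein_mask]) if vein_mask.any() else np.zeros(0, np.int64)
    return StraightenResult(new_level, temp02_ids, len(scales), scales)


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------

def _principal_length_vec(n, sr, sc, srr, scc, src) -> np.ndarray:
    var_r = srr / n - (sr / n) ** 2
    var_c = scc / n - (sc / n) ** 2
    cov = src / n - (sr / n) * (sc / n)
    half_tr = 0.5 * (var_r + var_c)
    disc = np.sqrt((0.5 * (var_r - var_c)) ** 2 + cov**2)
    lam1 = half_tr + disc
    lam2 = np.maximum(half_tr - disc, 0.0)
    collinear = lam2 <= 1e-12
    gamma = np.where(collinear, n, np.sqrt(lam1 / np.where(collinear, 1.0, lam2)))
    gamma = np.minimum(gamma, n)
    return np.sqrt(n * gamma)


def grow_gaps(
    level: SegmentationLevel,
    cfg: ReconnectionConfig | None = None,
    seed_ids: Sequence[int] | np.ndarray | None = None,
) -> GrowResult:
    """Grow straight segments across background gaps, cycle by cycle.

    ``seed_ids`` are the temp02 objects; every other pixel of the level is
    treated as mergeable background (pixelised, as by chessboard
    segmentation with tile 1).  See the module docstring for the growth
    rule.  Segments that become 4-adjacent are merged in the returned
    level; the remaining background is a single object with the highest id.
    """
    cfg = cfg or ReconnectionConfig()
    if seed_ids is None:
        raise ValueError("grow_gaps requires the temp02 seed object ids")
    seeds = np.asarray(list(seed_ids), dtype=np.int64)
    h, w = level.labels.shape
    img = level.image

    # Unit bookkeeping: unit = one temp02 segment (growth geometry is per
    # unit even after output-level merging).
    unit = np.full((h, w), -1, dtype=np.int64)
    for k, sid in enumerate(seeds):
        unit[level.labels == sid] = k
    nu = seeds.size
    grown = np.zeros((h, w), dtype=bool)
    if nu == 0 or not (unit < 0).any():
        vein_ids = np.arange(nu)
        return GrowResult(level, vein_ids, grown, 0, [], 0)

    inside = unit >= 0
    uf = np.arange(nu)  # union-find over units for the output level

    def find(i: int) -> int:
        while uf[i] != i:
            uf[i] = uf[uf[i]]
            i = uf[i]
        return i

    def neighbours_flat(f: np.ndarray) -> np.ndarray:
        """4-neighbour flat indices of flat pixel indices (clipped)."""
        r, c = f // w, f % w
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            ok = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
            out.append(nr[ok] * w + nc[ok])
        return np.concatenate(out) if out else np.zeros(0, np.int64)

    unit_flat = unit.ravel()
    comp0, _ = ndimage.label(inside, structure=FOUR_CONNECTED)  # pre-growth comps
    added_per_cycle: list[int] = []

    rho = int(cfg.window_radius)
    grown_flat = grown.ravel()
    moment_cache: dict[int, tuple[int, list]] = {}
    # A unit whose ring accepted nothing can never accept again (its own
    # pixels are unchanged and candidate sets only shrink), so skip it.
    stalled: set[int] = set()

    def _window_moments(px: np.ndarray):
        """Integral images of the unit indicator and coordinate moments,
        restricted to the unit's bounding box plus the window margin.
        Returns (origin, stack)."""
        pr, pc = px // w, px % w
        r_org = max(int(pr.min()) - rho - 2, 0)
        c_org = max(int(pc.min()) - rho - 2, 0)
        r_end = min(int(pr.max()) + rho + 3, h)
        c_end = min(int(pc.max()) + rho + 3, w)
        sh, sw = r_end - r_org, c_end - c_org
        mask = np.zeros((sh, sw))
        mask[pr - r_org, pc - c_org] = 1.0
        rr, cc = np.indices((sh, sw), dtype=np.float64)
        rr += r_org
        cc += c_org
        stack = []
        for m in (mask, mask * rr, mask * cc, mask * rr * rr,
                  mask * cc * cc, mask * rr * cc):
            ii = np.zeros((sh + 1, sw + 1))
            ii[1:, 1:] = np.cumsum(np.cumsum(m, axis=0), axis=1)
            stack.append(ii)
        return (r_org, c_org), stack

    def _box(ii: np.ndarray, r0, r1, c0, c1) -> np.ndarray:
        # Half-open boxes [r0, r1) x [c0, c1), in subdomain coordinates.
        return ii[r1, c1] - ii[r0, c1] - ii[r1, c0] + ii[r0, c0]

    for _cycle in range(cfg.growth_cycles):
        added = 0
        rounds = max(1, int(round(cfg.growth_cap_rings)))
        for _ring in range(rounds):
            for u in range(nu):
                if u in stalled:
                    continue
                px = np.flatnonzero(unit_flat == u)
                if px.size == 0:
                    stalled.add(u)
                    continue
                nb = neighbours_flat(px)
                cand = np.unique(nb[unit_flat[nb] < 0])
                if cand.size == 0:
                    stalled.add(u)
                    continue
                cached = moment_cache.get(u)
                if cached is not None and cached[0] == px.size:
                    (r_org, c_org), ii = cached[1]
                else:
                    origin_stack = _window_moments(px)
                    moment_cache[u] = (px.size, origin_stack)
                    (r_org, c_org), ii = origin_stack
                cr = cand // w
                cc_ = cand % w
                r0 = np.maximum(cr - rho, 0) - r_org
                r1 = np.minimum(cr + rho + 1, h) - r_org
                c0 = np.maximum(cc_ - rho, 0) - c_org
                c1 = np.minimum(cc_ + rho + 1, w) - c_org
                sh = ii[0].shape[0] - 1
                sw = ii[0].shape[1] - 1
                r0 = np.clip(r0, 0, sh)
                r1 = np.clip(r1, 0, sh)
                c0 = np.clip(c0, 0, sw)
                c1 = np.clip(c1, 0, sw)
                n_l = _box(ii[0], r0, r1, c0, c1)
                sr = _box(ii[1], r0, r1, c0, c1)
                sc = _box(ii[2], r0, r1, c0, c1)
                srr = _box(ii[3], r0, r1, c0, c1)
                scc = _box(ii[4], r0, r1, c0, c1)
                src = _box(ii[5], r0, r1, c0, c1)
                nonempty = n_l > 0
                sl = np.ones(cand.size)
                sl[nonempty] = _principal_length_vec(
                    n_l[nonempty],
                    sr[nonempty],
                    sc[nonempty],
                    srr[nonempty],
                    scc[nonempty],
                    src[nonempty],
                )
                fr = cr.astype(float)
                fc = cc_.astype(float)
                tl = _principal_length_vec(
                    n_l + 1,
                    sr + fr,
                    sc + fc,
                    srr + fr * fr,
                    scc + fc * fc,
                    src + fr * fc,
                )
                # TL - SL > 0 with the trivial sqrt(n) area inflation
                # removed: any added pixel raises sqrt(n * gamma) by about
                # SL/2n even when it makes the object less elongated, so a
                # genuine axial advance must also raise the local
                # elongation, i.e. beat SL * sqrt((n+1)/n) by a noise
                # margin.  Lateral and jagged-boundary candidates fail this.
                gain = tl - sl * np.sqrt((n_l + 1.0) / np.maximum(n_l, 1.0))
                accept = nonempty & (gain > cfg.min_elongation_gain)
                if not accept.any():
                    stalled.add(u)
                    continue
                sel = cand[accept]
                unit_flat[sel] = u
                grown_flat[sel] = True
                added += int(sel.size)
        added_per_cycle.append(added)

        # Merge units that became 4-adjacent (output bookkeeping).
        ug = unit_flat.reshape(h, w)
        for a, b in ((ug[:, :-1], ug[:, 1:]), (ug[:-1, :], ug[1:, :])):
            m = (a >= 0) & (b >= 0) & (a != b)
            for x, y in zip(a[m].tolist(), b[m].tolist()):
                rx, ry = find(x), find(y)
                if rx != ry:
                    uf[max(rx, ry)] = min(rx, ry)

    # Roll back growth that spliced nothing: a grown pixel is kept only if
    # it lies on a shortest path, through grown pixels, between two
    # distinct pre-growth vein components.  Free vein tips therefore end
    # where they ended before growth, and each closed gap keeps a tight
    # bridge instead of every exploratory pixel.
    pruned = 0
    gflat = np.flatnonzero(grown.ravel())
    if gflat.size:
        gindex = {int(f): i for i, f in enumerate(gflat)}
        ng = gflat.size
        # Grown-to-grown adjacency and grown-to-component contacts.
        adj: list[list[int]] = [[] for _ in range(ng)]
        contacts: dict[int, list[int]] = {}
        comp0_flat = comp0.ravel()
        for i, f in enumerate(gflat):
            for fn in neighbours_flat(np.asarray([f], dtype=np.int64)).tolist():
                j = gindex.get(int(fn))
                if j is not None:
                    adj[i].append(j)
                elif comp0_flat[fn] > 0:
                    contacts.setdefault(int(comp0_flat[fn]), []).append(i)
        dists: dict[int, np.ndarray] = {}
        for cid, seeds_i in contacts.items():
            d = np.full(ng, -1, dtype=np.int64)
            frontier = sorted(set(seeds_i))
            for i in frontier:
                d[i] = 1
            while frontier:
                nxt = []
                for i in frontier:
                    for j in adj[i]:
                        if d[j] < 0:
                            d[j] = d[i] + 1
                            nxt.append(j)
                frontier = nxt
            dists[cid] = d
        keep = np.zeros(ng, dtype=bool)
        cids = sorted(dists)
        for ai in range(len(cids)):
            for bi in range(ai + 1, len(cids)):
                da, db = dists[cids[ai]], dists[cids[bi]]
                both = (da > 0) & (db > 0)
                if not both.any():
                    continue
                total = da[both] + db[both]
                if total.min() > cfg.max_bridge_px:
                    continue  # far too long for an occlusion gap: not kept
                path = np.flatnonzero(both)[total == total.min()]
                # Prefer the straight chord between the two contacts when
                # the grown field covers it: the meeting growth fronts can
                # be laterally offset, and the raw shortest path then bows
                # around that offset instead of following the vein line.
                pa = int(gflat[path[np.argmin(da[path])]])
                pb = int(gflat[path[np.argmin(db[path])]])
                rr_, cc_ = draw_line(pa // w, pa % w, pb // w, pb % w)
                chord = rr_ * w + cc_
                on_grown = np.isin(chord, gflat)
                covered = on_grown | (comp0.ravel()[chord] > 0)
                if covered.all():
                    chord_idx = [gindex[int(f)] for f in chord[on_grown]]
                    keep[chord_idx] = True
                    keep[path[da[path] == 1]] = True
                    keep[path[db[path] == 1]] = True
                else:
                    keep[path] = True
        rollback = np.zeros(h * w, dtype=bool)
        rollback[gflat[~keep]] = True
        rollback = rollback.reshape(h, w)
        pruned += int(np.count_nonzero(rollback))
        grown[rollback] = False
        unit_flat[rollback.ravel()] = -1

    # Output level: merged unit groups, background as one trailing object.
    roots = np.array([find(i) for i in range(nu)])
    _, group = np.unique(roots, return_inverse=True)
    ngroups = int(group.max()) + 1 if nu else 0
    out = np.full(h * w, ngroups, dtype=np.int32)  # background id
    iv = unit_flat >= 0
    out[iv] = group[unit_flat[iv]].astype(np.int32)
    new_level = SegmentationLevel(out.reshape(h, w), img)
    return GrowResult(
        new_level,
        np.arange(ngroups),
        grown,
        cfg.growth_cycles,
        added_per_cycle,
        pruned,
    )


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def reconnect(
    level: SegmentationLevel,
    class_map: ClassMap | Sequence[int] | np.ndarray,
    cfg: ReconnectionConfig | None = None,
) -> ReconnectResult:
    """Straighten the classified veins, then grow them across gaps."""
    cfg = cfg or ReconnectionConfig()
    if isinstance(class_map, ClassMap):
        vein_ids = class_map.vein_ids
    else:
        vein_ids = np.asarray(list(class_map), dtype=np.int64)
    if vein_ids.size == 0:
        return ReconnectResult(level, np.zeros(0, dtype=np.int64), None, None)
    sr = straighten(level, vein_ids, cfg)
    gr = grow_gaps(sr.level, cfg, seed_ids=sr.temp02_ids)
    return ReconnectResult(gr.level, gr.vein_ids, sr, gr)
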