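"""Synthetic cleared-leaf micrographs with known venation ground truth.

The generator emulates what a toluidine-blue-stained, NaOH-cleared leaf
looks like under a compound microscope at 40x: bright, red-shifted
curvilinear veins over a darker textured mesophyll, with compact clutter
(stomata / guard-cell outlines) and, optionally, vein-interrupting
occlusions where trichomes crossed the vein.  Two venation architectures
are supported: *netted* (dicot-like midrib with branching secondaries and
tertiaries) and *parallel* (monocot-like longitudinal veins).

Every scene records its exact ground truth: the rendered vein mask, the
one-pixel centreline skeleton, the calibrated total vein length, and the
list of occlusion gaps (the truth keeps the full network, so reconnection
can be scored against it).  A scene is a pure function of its configuration
and seed.

Intensity model: per pixel, a target brightness B and red value R are drawn
from the class distributions and the green/blue bands are set to
(3B - R)/2 -+ a small split term, so pixel brightness is exactly B before
noise.  The default vein distributions sit inside the standard
classification thresholds (brightness 245 +- 3, red 205 +- 6, which
requires green/blue values above 255 — the raster is therefore written at
16-bit depth and is meant to be contrast-stretched before classification);
the background sits well outside (brightness 120 +- 20, red 140 +- 15),
with a spatially correlated cellular texture component.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .density_eval import skeleton_length_px
from .raster_io import DEFAULT_FIELD_MM, CalibratedImage


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic micrograph.

    Sizes are (rows, cols); the field of view defaults to the 40x reference
    field.  ``vein_widths`` are the rendered stroke widths in px of the
    midrib, secondary and tertiary veins (at the default calibration one
    pixel is ~4.3 um, so widths 7/5/3 px correspond to ~30/21/13 um veins).
    ``gap_len_px`` is the inclusive range of centreline pixels occluded per
    gap; occlusions are placed on prominent veins (order <= 1), must truly
    disconnect the network, and leave at least ``min_flank_px`` rendered
    pixels on every flank.  With ``clutter_like_veins`` the clutter blobs take the vein
    intensity distribution ("hard mode": only the geometric rule can reject
    them); by default they are bright but below the vein brightness window.
    """

    venation: str = "netted"
    size_px: tuple[int, int] = (383, 512)
    field_mm: tuple[float, float] = DEFAULT_FIELD_MM
    vein_brightness: tuple[float, float] = (245.0, 3.0)
    vein_red: tuple[float, float] = (205.0, 6.0)
    background_brightness: tuple[float, float] = (120.0, 20.0)
    background_red: tuple[float, float] = (140.0, 15.0)
    vein_widths: tuple[int, int, int] = (7, 5, 3)
    n_secondaries: int = 13
    n_tertiaries: int = 30
    n_parallel: int = 4
    n_gaps: int = 0
    gap_len_px: tuple[int, int] = (2, 6)
    min_flank_px: int = 1200
    n_clutter: int = 40
    clutter_radius: tuple[int, int] = (2, 4)
    clutter_brightness: tuple[float, float] = (200.0, 8.0)
    clutter_red: tuple[float, float] = (205.0, 10.0)
    clutter_like_veins: bool = False
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.venation not in ("netted", "parallel"):
            raise ValueError("venation must be 'netted' or 'parallel'")
        if min(self.size_px) < 32:
            raise ValueError("scene must be at least 32 px on a side")
        if min(self.field_mm) <= 0:
            raise ValueError("field dimensions must be positive")
        if min(self.vein_widths) < 1:
            raise ValueError("vein widths must be >= 1 px")
        if self.gap_len_px[0] < 1 or self.gap_len_px[0] > self.gap_len_px[1]:
            raise ValueError("gap_len_px must be an increasing range from >= 1")


@dataclasses.dataclass(frozen=True)
class Stroke:
    """One drawn vein: branching order and its 8-connected centreline."""

    order: int                # 0 midrib, 1 secondary, 2 tertiary
    width_px: int
    chain: np.ndarray         # (m, 2) int (row, col), consecutive neighbours


@dataclasses.dataclass(frozen=True)
class Gap:
    """A trichome occlusion cut into one stroke's rendering."""

    stroke_index: int
    chain_start: int          # first occluded centreline index
    length_px: int            # occluded centreline pixels
    anchor_a: tuple[int, int]  # surviving centreline pixel before the cut
    anchor_b: tuple[int, int]  # surviving centreline pixel after the cut
    cut_pixels: np.ndarray    # (m, 2) pixels removed from the rendered mask


@dataclasses.dataclass(frozen=True)
class SyntheticScene:
    image: CalibratedImage
    truth_mask: np.ndarray        # full network, gaps NOT removed
    truth_skeleton: np.ndarray    # full centreline network
    truth_length_mm: float
    rendered_mask: np.ndarray     # network as painted (gaps removed)
    gap_list: tuple[Gap, ...]
    strokes: tuple[Stroke, ...]
    config: SceneConfig

    @property
    def truth_density_mm_per_mm2(self) -> float:
        return self.truth_length_mm / self.image.area_mm2


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _polyline_chain(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """8-connected pixel chain through integer vertices, clipped to shape."""
    pts = []
    v = np.rint(vertices).astype(int)
    v[:, 0] = np.clip(v[:, 0], 0, shape[0] - 1)
    v[:, 1] = np.clip(v[:, 1], 0, shape[1] - 1)
    for (r0, c0), (r1, c1) in zip(v[:-1], v[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        pts.append(np.stack([rr, cc], axis=1)[:-1] if len(rr) > 1 else
                   np.stack([rr, cc], axis=1))
    pts.append(v[-1:][:, :2])
    chain = np.concatenate(pts, axis=0)
    # Drop consecutive duplicates produced by clipping.
    keep = np.ones(len(chain), dtype=bool)
    keep[1:] = (np.abs(np.diff(chain, axis=0)).max(axis=1)) > 0
    return chain[keep]


def _wavy_path(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: float,
    length: float,
    shape: tuple[int, int],
    *,
    wobble_sd: float = 0.06,
    step: float = 12.0,
    margin: int = 4,
    avoid: np.ndarray | None = None,
    parent_zone: np.ndarray | None = None,
    other_tips: list | None = None,
) -> np.ndarray:
    """Vertex list of a gently curving path of roughly the given length.

    The heading performs a small random walk (sd ``wobble_sd`` radians per
    step), which produces realistic, locally near-straight veins.  The path
    stops early at the image margin and before entering the ``avoid`` zone
    around already drawn veins, so the generated networks have freely
    ending veinlets (non-reticulate venation) and never cross each other.
    The ``parent_zone`` (the avoid zone of the stroke this one branches
    from) is exempt while the path escapes it, but re-entering it later
    also ends the path — a branch leaves its parent once and never curls
    back into it.
    """
    pos = start.astype(float).copy()
    heading = direction
    verts = [pos.copy()]
    travelled = 0.0
    exited_parent = parent_zone is None
    blocked = False
    while travelled < length:
        d = min(step, length - travelled)
        heading += rng.normal(0.0, wobble_sd)
        pos = pos + d * np.array([math.sin(heading), math.cos(heading)])
        if not (margin <= pos[0] < shape[0] - margin and margin <= pos[1] < shape[1] - margin):
            break
        pr, pc = int(round(pos[0])), int(round(pos[1]))
        in_parent = parent_zone is not None and parent_zone[pr, pc]
        if avoid is not None and avoid[pr, pc] and not in_parent:
            blocked = True
            break
        if in_parent and exited_parent:
            blocked = True
            break
        if not in_parent:
            exited_parent = True
        verts.append(pos.copy())
        travelled += d
    if parent_zone is not None and not exited_parent:
        # The branch never escaped its parent's exclusion zone: it would
        # hug the parent and end aimed at it from point-blank range, which
        # no free veinlet does.  Discard it.
        return np.asarray(verts[:1])
    if blocked and len(verts) > 2:
        # A tip stopped by another vein's exclusion zone points straight at
        # that vein; real veinlets end freely in the middle of an areole,
        # so retract the ending by one step.
        verts = verts[:-1]
    if other_tips:
        while len(verts) > 2 and any(
            np.hypot(*(verts[-1] - t)) < 18.0 for t in other_tips
        ):
            verts = verts[:-1]
    return np.asarray(verts)


def _netted_strokes(rng: np.random.Generator, cfg: SceneConfig) -> list[Stroke]:
    h, w = cfg.size_px
    strokes: list[Stroke] = []

    # Midrib: left edge to right edge with a gentle bow.
    amp = rng.uniform(h / 30, h / 14)
    phase = rng.uniform(0, 2 * math.pi)
    freq = rng.uniform(0.6, 1.1)
    cs = np.arange(0, w, 8, dtype=float)
    if cs[-1] != w - 1:
        cs = np.append(cs, w - 1)
    rs = h / 2 + amp * np.sin(2 * math.pi * freq * cs / w + phase)
    midrib = _polyline_chain(np.stack([rs, cs], axis=1), (h, w))
    strokes.append(Stroke(0, cfg.vein_widths[0], midrib))

    avoid = np.zeros((h, w), dtype=bool)

    def _zone(chain: np.ndarray) -> np.ndarray:
        canvas = np.ones((h, w), dtype=bool)
        canvas[chain[:, 0], chain[:, 1]] = False
        return ndimage.distance_transform_edt(canvas) <= 20.0

    zones: dict[int, np.ndarray] = {}
    tips: list[np.ndarray] = []

    def _occupy(idx: int, chain: np.ndarray) -> None:
        zones[idx] = _zone(chain)
        avoid[:] |= zones[idx]
        tips.append(chain[-1].astype(float))

    _occupy(0, midrib)

    # Secondaries: branch off the midrib at acute angles, alternating sides.
    m = len(midrib)
    attach = np.linspace(0.08, 0.92, cfg.n_secondaries) * (m - 1)
    for i, t in enumerate(attach):
        j = int(t)
        j2 = min(j + 8, m - 1)
        tangent = math.atan2(
            float(midrib[j2, 0] - midrib[j, 0]), float(midrib[j2, 1] - midrib[j, 1])
        )
        side = 1 if i % 2 == 0 else -1
        ang = tangent + side * math.radians(rng.uniform(35, 50))
        length = rng.uniform(0.40, 0.65) * h
        verts = _wavy_path(
            rng, midrib[j].astype(float), ang, length, (h, w),
            avoid=avoid, parent_zone=zones[0], other_tips=tips,
        )
        if len(verts) >= 2:
            chain = _polyline_chain(verts, (h, w))
            strokes.append(Stroke(1, cfg.vein_widths[1], chain))
            _occupy(len(strokes) - 1, chain)

    # Tertiaries: short branches off the secondaries.
    secondaries = [(i, s) for i, s in enumerate(strokes) if s.order == 1]
    for k in range(cfg.n_tertiaries):
        if not secondaries:
            break
        pi, parent = secondaries[int(rng.integers(len(secondaries)))]
        ch = parent.chain
        if len(ch) < 24:
            continue
        j = int(rng.integers(8, len(ch) - 12))
        j2 = min(j + 6, len(ch) - 1)
        tangent = math.atan2(
            float(ch[j2, 0] - ch[j, 0]), float(ch[j2, 1] - ch[j, 1])
        )
        side = 1 if k % 2 == 0 else -1
        ang = tangent + side * math.radians(rng.uniform(35, 50))
        length = rng.uniform(30, 70)
        verts = _wavy_path(
            rng, ch[j].astype(float), ang, length, (h, w), step=8.0,
            avoid=avoid, parent_zone=zones[pi], other_tips=tips,
        )
        if len(verts) >= 2:
            chain = _polyline_chain(verts, (h, w))
            strokes.append(Stroke(2, cfg.vein_widths[2], chain))
            _occupy(len(strokes) - 1, chain)
    return strokes


def _parallel_strokes(rng: np.random.Generator, cfg: SceneConfig) -> list[Stroke]:
    h, w = cfg.size_px
    strokes: list[Stroke] = []
    rows0 = (np.arange(cfg.n_parallel) + 0.5) / cfg.n_parallel * h
    cs = np.arange(0, w, 8, dtype=float)
    if cs[-1] != w - 1:
        cs = np.append(cs, w - 1)
    for r0 in rows0:
        amp = rng.uniform(1.0, h / 60)
        phase = rng.uniform(0, 2 * math.pi)
        rs = r0 + amp * np.sin(2 * math.pi * cs / w + phase) + rng.normal(0, 0.3)
        rs = np.clip(rs, 2, h - 3)
        chain = _polyline_chain(np.stack([rs, cs], axis=1), (h, w))
        strokes.append(Stroke(1, cfg.vein_widths[1], chain))
    return strokes


def _render(strokes: Sequence[Stroke], shape) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise strokes: (mask at stroke widths, centreline skeleton)."""
    skel = np.zeros(shape, dtype=bool)
    mask = np.zeros(shape, dtype=bool)
    by_width: dict[int, np.ndarray] = {}
    for s in strokes:
        skel[s.chain[:, 0], s.chain[:, 1]] = True
        canvas = by_width.setdefault(s.width_px, np.zeros(shape, dtype=bool))
        canvas[s.chain[:, 0], s.chain[:, 1]] = True
    for width, canvas in by_width.items():
        r = (width - 1) // 2
        if r > 0:
            canvas = ndimage.binary_dilation(
                canvas, structure=_disk_structure(r)
            )
        mask |= canvas
    return mask, skel


def _disk_structure(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy**2 + xx**2 <= radius**2 + 0.5


# ---------------------------------------------------------------------------
# Occlusions
# ---------------------------------------------------------------------------

def _cut_gaps(
    rng: np.random.Generator,
    strokes: Sequence[Stroke],
    rendered: np.ndarray,
    n_gaps: int,
    gap_len_range: tuple[int, int],
    existing: Sequence[Gap] = (),
    min_flank_px: int = 1200,
) -> list[Gap]:
    """Cut ``n_gaps`` occlusions into the rendered mask (in place).

    Occlusions are placed on the prominent veins (branching order <= 1):
    a trichome is an order of magnitude wider than the finest veinlets, so
    its interruption is observable — and reconnectable — only on veins that
    remain substantial on both flanks.  A candidate site is accepted only
    when, after the cut, every vein piece flanking any gap still holds at
    least ``min_flank_px`` rendered pixels.
    """
    eligible = [
        i
        for i, s in enumerate(strokes)
        if s.order <= 1 and len(s.chain) >= 2 * (gap_len_range[1] + 16)
    ]
    if not eligible:
        raise ValueError("no stroke is long enough to host an occlusion gap")
    used: dict[int, list[tuple[int, int]]] = {}
    all_anchors: list[tuple[int, int]] = []
    for g in existing:
        used.setdefault(g.stroke_index, []).append(
            (g.chain_start, g.chain_start + g.length_px)
        )
        all_anchors += [g.anchor_a, g.anchor_b]
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    gaps: list[Gap] = []
    attempts = 0
    while len(gaps) < n_gaps:
        attempts += 1
        if attempts > 1500 * n_gaps:
            raise ValueError("could not place the requested occlusion gaps")
        si = eligible[int(rng.integers(len(eligible)))]
        s = strokes[si]
        glen = int(rng.integers(gap_len_range[0], gap_len_range[1] + 1))
        margin = s.width_px // 2 + 3
        lo, hi = margin, len(s.chain) - margin - glen
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        window = (start - margin, start + glen + margin)
        if any(w0 < window[1] and window[0] < w1 for w0, w1 in used.get(si, [])):
            continue
        cut_r = max(1, s.width_px // 2)
        cut = np.zeros(rendered.shape, dtype=bool)
        seg = s.chain[start : start + glen]
        cut[seg[:, 0], seg[:, 1]] = True
        cut = ndimage.binary_dilation(cut, structure=_disk_structure(cut_r))
        anchor_a = tuple(int(x) for x in s.chain[start - cut_r - 1])
        anchor_b = tuple(int(x) for x in s.chain[start + glen + cut_r])
        trial = rendered & ~cut
        # 8-connectivity: a corner-touching remnant still connects the
        # flanks for any downstream pixel analysis, so it is not a cut.
        comp, _ = ndimage.label(trial, structure=np.ones((3, 3), dtype=bool))
        sizes = np.bincount(comp.ravel())
        # The cut must truly interrupt the network (no detour around it),
        # and every flank of every gap must stay observable.
        if comp[anchor_a] == comp[anchor_b]:
            continue
        ok = True
        for ar, ac in all_anchors + [anchor_a, anchor_b]:
            cid = comp[ar, ac]
            if cid == 0 or sizes[cid] < min_flank_px:
                ok = False
                break
        if not ok:
            continue
        removed = np.argwhere(cut & rendered)
        rendered[cut] = False
        used.setdefault(si, []).append(window)
        all_anchors += [anchor_a, anchor_b]
        gaps.append(
            Gap(
                stroke_index=si,
                chain_start=start,
                length_px=glen,
                anchor_a=anchor_a,
                anchor_b=anchor_b,
                cut_pixels=removed,
            )
        )
    return gaps


# ---------------------------------------------------------------------------
# Intensity painting
# ---------------------------------------------------------------------------

def _sample_rgb(
    rng: np.random.Generator,
    npix: int,
    brightness: tuple[float, float],
    red: tuple[float, float],
) -> np.ndarray:
    """(npix, 3) float samples with exact per-pixel brightness control."""
    b = rng.normal(brightness[0], brightness[1], npix)
    r = rng.normal(red[0], red[1], npix)
    gb = (3.0 * b - r) / 2.0
    split = rng.normal(0.0, 2.0, npix)
    return np.stack([r, gb + split, gb - split], axis=1)


def _background_field(
    rng: np.random.Generator, shape: tuple[int, int], cfg: SceneConfig
) -> np.ndarray:
    """(H, W, 3) mesophyll background with cellular texture.

    Brightness and red values share a spatially correlated component
    (Gaussian random field, correlation length ~ one mesophyll cell of
    ~10 px at the default calibration) plus independent pixel noise; the
    marginal distributions keep the configured means and SDs.
    """
    h, w = shape
    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), 3.5)
    sd = float(field.std())
    field = field / sd if sd > 0 else field
    bm, bs = cfg.background_brightness
    rm, rs = cfg.background_red
    b = bm + bs * (0.75 * field + 0.66 * rng.standard_normal((h, w)))
    r = rm + rs * (0.60 * field + 0.80 * rng.standard_normal((h, w)))
    gb = (3.0 * b - r) / 2.0
    split = rng.normal(0.0, 2.0, (h, w))
    return np.stack([r, gb + split, gb - split], axis=2)


def _paint(
    rng: np.random.Generator,
    cfg: SceneConfig,
    rendered: np.ndarray,
    truth_mask: np.ndarray,
) -> CalibratedImage:
    h, w = cfg.size_px
    vals = _background_field(rng, (h, w), cfg)

    # Clutter blobs (stomata / guard cells), kept clear of the vein network.
    keepout = ndimage.binary_dilation(truth_mask, structure=_disk_structure(8))
    cb = cfg.vein_brightness if cfg.clutter_like_veins else cfg.clutter_brightness
    cr = cfg.vein_red if cfg.clutter_like_veins else cfg.clutter_red
    placed = 0
    tries = 0
    while placed < cfg.n_clutter and tries < 50 * max(cfg.n_clutter, 1):
        tries += 1
        r0 = int(rng.integers(4, h - 4))
        c0 = int(rng.integers(4, w - 4))
        if keepout[r0, c0]:
            continue
        radius = int(rng.integers(cfg.clutter_radius[0], cfg.clutter_radius[1] + 1))
        rr, cc = draw_disk((r0, c0), radius, shape=(h, w))
        vals[rr, cc] = _sample_rgb(rng, len(rr), cb, cr)
        placed += 1

    nv = int(np.count_nonzero(rendered))
    vals[rendered] = _sample_rgb(rng, nv, cfg.vein_brightness, cfg.vein_red)

    if cfg.noise_sd > 0:
        vals = vals + rng.normal(0.0, cfg.noise_sd, vals.shape)
    pixels = np.clip(np.rint(vals), 0, None).astype(np.uint16)
    return CalibratedImage(pixels, cfg.field_mm[0], cfg.field_mm[1])


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def generate(cfg: SceneConfig) -> SyntheticScene:
    """Generate one scene: geometry, occlusions, then intensities.

    Deterministic: the same config (including its seed) yields a
    bit-identical scene.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.size_px
    strokes = (
        _netted_strokes(rng, cfg)
        if cfg.venation == "netted"
        else _parallel_strokes(rng, cfg)
    )
    truth_mask, truth_skel = _render(strokes, (h, w))
    rendered = truth_mask.copy()
    gaps: list[Gap] = []
    if cfg.n_gaps > 0:
        gaps = _cut_gaps(
            rng, strokes, rendered, cfg.n_gaps, cfg.gap_len_px,
            min_flank_px=cfg.min_flank_px,
        )
    image = _paint(rng, cfg, rendered, truth_mask)
    pixel_mm = cfg.field_mm[0] / w
    return SyntheticScene(
        image=image,
        truth_mask=truth_mask,
        truth_skeleton=truth_skel,
        truth_length_mm=skeleton_length_px(truth_skel) * pixel_mm,
        rendered_mask=rendered,
        gap_list=tuple(gaps),
        strokes=tuple(strokes),
        config=cfg,
    )


def gap_closure(final_mask: np.ndarray, scene: SyntheticScene, snap_px: int = 3) -> list[bool]:
    """Audit which occlusion gaps an extracted vein mask has closed.

    A gap counts as closed when its two anchor pixels (the surviving
    centreline pixels flanking the cut) fall in the same 8-connected
    component of ``final_mask``.  Anchors are snapped to the nearest mask
    pixel within ``snap_px`` (Chebyshev); an unsnappable anchor means the
    gap is open.
    """
    final_mask = np.asarray(final_mask, dtype=bool)
    comp, _ = ndimage.label(final_mask, structure=np.ones((3, 3), dtype=bool))
    h, w = final_mask.shape

    def snap(pt: tuple[int, int]) -> int:
        r, c = pt
        best, best_d = 0, None
        for dr in range(-snap_px, snap_px + 1):
            for dc in range(-snap_px, snap_px + 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and final_mask[rr, cc]:
                    d = max(abs(dr), abs(dc))
                    if best_d is None or d < best_d:
                        best, best_d = comp[rr, cc], d
        return best

    out = []
    for g in scene.gap_list:
        ca, cb = snap(g.anchor_a), snap(g.anchor_b)
        out.append(ca != 0 and ca == cb)
    return out


def perturb_with_occlusions(
    scene: SyntheticScene, n_gaps: int, gap_len_px: int | tuple[int, int]
) -> SyntheticScene:
    """Cut additional occlusion gaps into an existing scene.

    The truth retains the full network; only the rendered mask and the image
    change.  Repainting uses a stream derived from the scene seed and the
    number of gaps already present, so the operation is deterministic.
    ``n_gaps=0`` returns the scene unchanged.
    """
    if n_gaps == 0:
        return scene
    if isinstance(gap_len_px, int):
        gap_range = (gap_len_px, gap_len_px)
    else:
        gap_range = (int(gap_len_px[0]), int(gap_len_px[1]))
    rng = np.random.default_rng([scene.config.seed, len(scene.gap_list), 9173])
    rendered = scene.rendered_mask.copy()
    new_gaps = _cut_gaps(
        rng,
        scene.strokes,
        rendered,
        n_gaps,
        gap_range,
        existing=scene.gap_list,
        min_flank_px=scene.config.min_flank_px,
    )
    # Repaint the cut regions as background (the occluding trichome hides
    # the vein), with fresh noise only there.
    pixels = scene.image.pixels.astype(np.float64)
    cut = scene.rendered_mask & ~rendered
    ncut = int(np.count_nonzero(cut))
    vals = _sample_rgb(
        rng, ncut, scene.config.background_brightness, scene.config.background_red
    )
    if scene.config.noise_sd > 0:
        vals = vals + rng.normal(0.0, scene.config.noise_sd, vals.shape)
    pixels[cut] = vals
    image = CalibratedImage(
        np.clip(np.rint(pixels), 0, None).astype(np.uint16),
        scene.config.field_mm[0],
        scene.config.field_mm[1],
    )
    return dataclasses.replace(
        scene,
        image=image,
        rendered_mask=rendered,
        gap_list=scene.gap_list + tuple(new_gaps),
    )
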