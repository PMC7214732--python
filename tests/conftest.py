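import numpy as np
import pytest

from veinseg import CalibratedImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_image(pixels, field=(1.0, 1.0)):
    """CalibratedImage from an (H, W) or (H, W, 3) integer array."""
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return CalibratedImage(arr.astype(np.int32), field[0], field[1])


def brute_object_stats(labels, pixels, oid):
    """Recompute every per-object statistic directly from the pixel set."""
    mask = labels == oid
    rows, cols = np.nonzero(mask)
    vals = pixels[mask].astype(float)
    n = rows.size
    h, w = labels.shape
    border = 0
    for r, c in zip(rows, cols):
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w) or labels[rr, cc] != oid:
                border += 1
    return {
        "n": n,
        "mean": vals.mean(axis=0),
        "sd": vals.std(axis=0),  # population
        "border": border,
        "bbox": (rows.min(), cols.min(), rows.max() + 1, cols.max() + 1),
        "var_r": float(np.var(rows)),
        "var_c": float(np.var(cols)),
        "cov_rc": float(np.mean((rows - rows.mean()) * (cols - cols.mean()))),
    }


def brute_merge_cost(labels, pixels, a, b, params):
    """Spec-formula merge cost recomputed from raw pixels (oracle)."""
    sa = brute_object_stats(labels, pixels, a)
    sb = brute_object_stats(labels, pixels, b)
    merged = labels.copy()
    merged[labels == b] = a
    sab = brute_object_stats(merged, pixels, a)

    weights = np.asarray(params.band_weights)
    dh_color = float(
        weights
        @ (sab["n"] * sab["sd"] - sa["n"] * sa["sd"] - sb["n"] * sb["sd"])
    )

    def h_cmpct(s):
        return s["border"] / np.sqrt(s["n"])

    def h_smooth(s):
        r0, c0, r1, c1 = s["bbox"]
        return s["border"] / (2.0 * ((r1 - r0) + (c1 - c0)))

    d_cmpct = (
        sab["n"] * h_cmpct(sab) - sa["n"] * h_cmpct(sa) - sb["n"] * h_cmpct(sb)
    )
    d_smooth = (
        sab["n"] * h_smooth(sab) - sa["n"] * h_smooth(sa) - sb["n"] * h_smooth(sb)
    )
    cw = params.compactness_weight
    dh_shape = cw * d_cmpct + (1 - cw) * d_smooth
    return (1 - params.shape_weight) * dh_color + params.shape_weight * dh_shape
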