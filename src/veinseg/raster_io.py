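"""Reading, writing and preprocessing of calibrated leaf micrographs.

A micrograph is a 3-band (R, G, B) integer raster tied to a physical field of
view, so that pixel measurements can be converted to millimetres.  The default
field of view, 2.2013 x 1.6468 mm, corresponds to a compound microscope at
40x magnification.

The only preprocessing step offered is a percent linear contrast stretch: per
band, intensities at or below the lower clip quantile map to 0, at or above
the upper clip quantile map to 255, linearly in between.  This normalises the
intensity scale of micrographs taken under slightly different illumination so
that one set of classification thresholds can serve a whole batch.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

logger = logging.getLogger(__name__)

#: Field of view (width, height) in mm of the reference microscope at 40x.
DEFAULT_FIELD_MM: tuple[float, float] = (2.2013, 1.6468)


class CalibrationWarning(UserWarning):
    """Raised when the implied pixels are not square within tolerance."""


@dataclasses.dataclass(frozen=True)
class CalibratedImage:
    """A 3-band integer raster with a physical pixel size.

    Parameters
    ----------
    pixels:
        ``(height, width, 3)`` array of non-negative integer intensities.
        Any bit depth is accepted; 8-bit is assumed only after stretching.
    field_width_mm, field_height_mm:
        Physical size of the imaged field of view.  The pixel size is derived
        from the width (pixels are assumed square).
    """

    pixels: np.ndarray
    field_width_mm: float = DEFAULT_FIELD_MM[0]
    field_height_mm: float = DEFAULT_FIELD_MM[1]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) raster, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"intensities must be integer, got dtype {px.dtype}")
        if px.size and px.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.field_width_mm <= 0 or self.field_height_mm <= 0:
            raise ValueError("field dimensions must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def pixel_size_mm(self) -> float:
        """mm per pixel edge, derived from the field width."""
        return self.field_width_mm / self.width_px

    @property
    def area_mm2(self) -> float:
        """Physical area of the full field, in mm^2."""
        return self.width_px * self.height_px * self.pixel_size_mm**2

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        """Same calibration, new raster of the same width/height."""
        if pixels.shape[:2] != self.pixels.shape[:2]:
            raise ValueError("raster shape changed; calibration would be wrong")
        return dataclasses.replace(self, pixels=pixels)


def load_image(
    path: str | Path,
    field_width_mm: float = DEFAULT_FIELD_MM[0],
    field_height_mm: float = DEFAULT_FIELD_MM[1],
) -> CalibratedImage:
    """Read a TIFF or PNG micrograph and attach physical calibration.

    Grayscale inputs are replicated to three identical bands; an alpha
    channel, if present, is dropped.  If the field dimensions imply
    non-square pixels (width- and height-derived pixel sizes differ by more
    than 2 % relative), a :class:`CalibrationWarning` is emitted and the
    width-derived value is used.
    """
    path = Path(path)
    if field_width_mm <= 0 or field_height_mm <= 0:
        raise ValueError("field dimensions must be positive")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc

    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"unsupported band layout {arr.shape} in {path}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise IOError(f"expected integer intensities in {path}, got {arr.dtype}")

    h, w = arr.shape[:2]
    size_w = field_width_mm / w
    size_h = field_height_mm / h
    if abs(size_w - size_h) > 0.02 * size_w:
        warnings.warn(
            f"non-square pixels implied ({size_w:.6g} vs {size_h:.6g} mm); "
            "using the width-derived pixel size",
            CalibrationWarning,
            stacklevel=2,
        )
    return CalibratedImage(arr, field_width_mm, field_height_mm)


def save_image(img: CalibratedImage | np.ndarray, path: str | Path) -> None:
    """Write a raster as TIFF or PNG (8-bit if the values allow it)."""
    path = Path(path)
    arr = img.pixels if isinstance(img, CalibratedImage) else np.asarray(img)
    if arr.dtype != np.uint8 and arr.size and arr.max() <= 255:
        arr = arr.astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def nearest_rank_quantiles(
    values: np.ndarray, clip_fraction: float
) -> tuple[float, float]:
    """Lower/upper clip values by the nearest-rank rule on the sorted multiset.

    The lower value is the element of rank ``max(1, ceil(q*n))`` and the upper
    the element of rank ``ceil((1-q)*n)`` (1-based), which makes
    ``clip_fraction=0`` return the exact minimum and maximum.
    """
    v = np.sort(np.asarray(values).ravel())
    n = v.size
    lo_rank = max(1, math.ceil(clip_fraction * n))
    hi_rank = max(1, math.ceil((1.0 - clip_fraction) * n))
    return float(v[lo_rank - 1]), float(v[hi_rank - 1])


def linear_stretch(
    img: CalibratedImage, clip_fraction: float = 0.01
) -> CalibratedImage:
    """Percent linear contrast stretch, applied independently per band.

    Per band, values at or below the ``clip_fraction`` nearest-rank quantile
    map to 0, values at or above the ``1 - clip_fraction`` quantile map to
    255, with integer-rounded linear interpolation in between.  A constant
    band (degenerate quantiles) is returned unchanged with a logged warning.
    """
    if not 0.0 <= clip_fraction < 0.5:
        raise ValueError("clip_fraction must be in [0, 0.5)")
    out = np.empty(img.pixels.shape, dtype=np.int32)
    for b in range(3):
        band = img.pixels[:, :, b]
        lo, hi = nearest_rank_quantiles(band, clip_fraction)
        if hi == lo:
            logger.warning("band %d is constant; stretch left it unchanged", b)
            out[:, :, b] = band
            continue
        scaled = (band.astype(np.float64) - lo) * (255.0 / (hi - lo))
        out[:, :, b] = np.clip(np.rint(scaled), 0, 255).astype(np.int32)
    if out.size == 0 or out.max() <= 255:
        out = out.astype(np.uint8) if out.min() >= 0 else out
    return img.with_pixels(out)
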