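"""Per-organoid immunofluorescence quantification through the boundary mask.

The traced DIC boundary defines a spatial mask on the paired epifluorescence
frame (identical resolution and position).  Pixel codes 0–255 are scaled to
[0, 1] by division by 255 and summed inside the mask.  Two normalizations are
reported: *total* intensity divides the in-mask sum by the number of pixels
in the whole image (1,443,520 for a 1040x1388 frame), *mean* intensity
divides by the mask area in pixels.  Because the organoid occupies less than
the full frame, mean >= total always.

Cohort-wide values are rank-normalized to (rank - 0.5)/n, mapping any
distribution onto a uniform grid in the open interval (0, 1) — robust to the
skewed, dynamic-range-dependent distributions typical of fluorescence sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from invaspect.io import ImageMeta, RawBoundary

__all__ = [
    "K14Record",
    "read_intensity_image",
    "rasterize_mask",
    "total_intensity",
    "mean_intensity",
    "rank_normalize",
    "quantify_boundary",
]


@dataclass(frozen=True)
class K14Record:
    """Intensity summary for one organoid mask on one image."""

    total_k14: float  # in-mask scaled sum / image pixel count
    mean_k14: float  # in-mask scaled sum / mask pixel count, in [0, 1]
    mask_area_px: int


def read_intensity_image(path: str | Path) -> np.ndarray:
    """Read a grayscale intensity image as uint8.

    16-bit inputs are rescaled by their code-value maximum with a warning
    (the acquisition convention here is 8-bit, 0 = no fluorescence,
    255 = saturation).
    """
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse an RGB-coded grayscale image
        img = img[..., 0]
    if img.dtype == np.uint16:
        warnings.warn("16-bit image rescaled to 8-bit by max code value", stacklevel=2)
        img = (img.astype(float) / 65535.0 * 255.0).round().astype(np.uint8)
    return img.astype(np.uint8)


def rasterize_mask(boundary: RawBoundary | np.ndarray, shape: tuple[int, int] | ImageMeta) -> np.ndarray:
    """Rasterize the closed polygon to a boolean pixel mask.

    Pixel (r, c) is in-mask iff its center (c + 0.5, r + 0.5) lies inside the
    polygon by the even-odd (crossing-number) rule.  Vertices outside the
    image bounds are clipped with a warning.
    """
    if isinstance(shape, ImageMeta):
        height, width = shape.height_px, shape.width_px
    else:
        height, width = shape
    v = boundary.vertices if isinstance(boundary, RawBoundary) else np.asarray(boundary, float)
    if np.any(v[:, 0] < 0) or np.any(v[:, 0] > width) or np.any(v[:, 1] < 0) or np.any(v[:, 1] > height):
        warnings.warn("boundary vertices outside image bounds clipped", stacklevel=2)
        v = np.column_stack([np.clip(v[:, 0], 0, width), np.clip(v[:, 1], 0, height)])

    # restrict work to the bounding box, then paste into the full frame
    r0 = max(int(np.floor(v[:, 1].min() - 0.5)), 0)
    r1 = min(int(np.ceil(v[:, 1].max() + 0.5)), height)
    c0 = max(int(np.floor(v[:, 0].min() - 0.5)), 0)
    c1 = min(int(np.ceil(v[:, 0].max() + 0.5)), width)
    mask = np.zeros((height, width), dtype=bool)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("boundary rasterizes to an empty mask")

    px = np.arange(c0, c1) + 0.5
    py = np.arange(r0, r1) + 0.5
    cx = px[None, :]  # pixel-center x per column
    cy = py[:, None]  # pixel-center y per row

    crossings = np.zeros((r1 - r0, c1 - c0), dtype=int)
    x1s, y1s = v[:, 0], v[:, 1]
    x2s, y2s = np.roll(x1s, -1), np.roll(y1s, -1)
    for x1, y1, x2, y2 in zip(x1s, y1s, x2s, y2s):
        if y1 == y2:
            continue  # horizontal edge never crosses a half-open scan ray
        straddle = (y1 > cy) != (y2 > cy)
        x_at = x1 + (cy - y1) * (x2 - x1) / (y2 - y1)
        crossings += straddle & (cx < x_at)
    box = (crossings % 2) == 1
    if not box.any():
        raise ValueError("boundary rasterizes to an empty mask")
    mask[r0:r1, c0:c1] = box
    return mask


def _scaled_mask_sum(image: np.ndarray, mask: np.ndarray) -> float:
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    return float(image[mask].astype(float).sum() / 255.0)


def total_intensity(image: np.ndarray, mask: np.ndarray) -> float:
    """In-mask scaled intensity sum divided by the image pixel count."""
    return _scaled_mask_sum(image, mask) / image.size


def mean_intensity(image: np.ndarray, mask: np.ndarray) -> float:
    """In-mask scaled intensity sum divided by the mask pixel count."""
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    return _scaled_mask_sum(image, mask) / area


def rank_normalize(values) -> np.ndarray:
    """Map values to (rank - 0.5)/n in (0, 1), ties given their average rank.

    Order-preserving and invariant to any strictly monotone transform of the
    inputs; with n distinct values the outputs are exactly {(r-0.5)/n}.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("rank_normalize requires at least one value")
    return (rankdata(values, method="average") - 0.5) / values.size


def quantify_boundary(boundary: RawBoundary, image: np.ndarray) -> K14Record:
    """Mask the image with the boundary and report total/mean intensity."""
    mask = rasterize_mask(boundary, image.shape)
    s = _scaled_mask_sum(image, mask)
    area = int(mask.sum())
    return K14Record(total_k14=s / image.size, mean_k14=s / area, mask_area_px=area)
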