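"""Fundus preprocessing: green channel, CLAHE, gamma, [-1, 1] standardization.

The network input is produced by a five-stage chain applied to each 8-bit
RGB fundus photograph:

1. extract the green channel (best vessel/background contrast);
2. CLAHE on the 8-bit channel, 8x8-pixel window, max slope 3.0;
3. min–max normalization of the values inside the FOV mask to [0, 1];
4. gamma transform v -> v**0.8 (lifts contrast in dark thin-vessel regions);
5. linear mapping of the FOV values to [-1, 1]; pixels outside the FOV are
   set to the background fill value -1.

High-resolution databases are bilinearly down-sampled before inference and
the prediction is up-scaled back before evaluation; FOV masks are eroded by
four pixels for all metric computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, transform

__all__ = [
    "FundusSample",
    "PreprocessedImage",
    "CLAHE_WINDOW",
    "CLAHE_MAX_SLOPE",
    "GAMMA",
    "FOV_EROSION_MARGIN",
    "preprocess",
    "erode_fov",
    "resample_image",
    "resample_pair",
    "restore_prediction",
]

CLAHE_WINDOW = 8          # CLAHE contextual window, pixels
CLAHE_MAX_SLOPE = 3.0     # histogram clip expressed as maximum CDF slope
CLAHE_NBINS = 256
GAMMA = 0.8               # gamma-transform exponent
FOV_EROSION_MARGIN = 4    # inward FOV erosion before evaluation, pixels
BACKGROUND_FILL = -1.0


@dataclass
class FundusSample:
    """One fundus photograph with its masks.

    ``rgb`` is an 8-bit HxWx3 image; ``fov`` and ``annotation`` are binary
    masks of the same height/width.  ``diameter_map`` carries the true
    per-pixel vessel caliber (px) when the sample is synthetic.
    """

    rgb: np.ndarray
    fov: np.ndarray
    annotation: np.ndarray | None = None
    diameter_map: np.ndarray | None = None
    db_tag: str = ""
    image_id: str = ""

    def __post_init__(self):
        self.fov = np.asarray(self.fov).astype(bool)
        if self.annotation is not None:
            self.annotation = np.asarray(self.annotation).astype(bool)
        if self.rgb.shape[:2] != self.fov.shape:
            raise ValueError("rgb and fov shapes disagree")
        if self.annotation is not None and self.annotation.shape != self.fov.shape:
            raise ValueError("annotation and fov shapes disagree")


@dataclass
class PreprocessedImage:
    """Standardized single-channel network input in [-1, 1]."""

    values: np.ndarray
    fov: np.ndarray
    scale_factor: int = 1


def _minmax_in_fov(values: np.ndarray, fov: np.ndarray):
    """Min–max normalize inside the FOV; returns (normalized, degenerate)."""
    inside = values[fov]
    vmin, vmax = float(inside.min()), float(inside.max())
    if vmax > vmin:
        return np.clip((values - vmin) / (vmax - vmin), 0.0, 1.0), False
    return np.zeros_like(values), True


def preprocess(sample: FundusSample) -> PreprocessedImage:
    """Run the five-stage preprocessing chain on one sample.

    Inside the FOV the output attains min -1.0 and max +1.0 (when the
    channel has at least two distinct values there); outside the FOV every
    pixel is the background fill -1.  A constant channel inside the FOV maps
    to 0 there (midpoint convention for the degenerate range).
    """
    rgb = np.asarray(sample.rgb)
    if rgb.dtype != np.uint8:
        raise ValueError("preprocess expects an 8-bit RGB image")
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("preprocess expects an HxWx3 RGB image")
    fov = sample.fov
    if not fov.any():
        raise ValueError("empty FOV mask")

    green = rgb[:, :, 1]
    # skimage's clip_limit is the clipped fraction of the tile pixel count;
    # a classical max slope S over `nbins` bins corresponds to S / nbins.
    eq = exposure.equalize_adapthist(
        green, kernel_size=CLAHE_WINDOW, clip_limit=CLAHE_MAX_SLOPE / CLAHE_NBINS,
        nbins=CLAHE_NBINS)
    v01, degen = _minmax_in_fov(eq, fov)
    if not degen:
        v01 = v01 ** GAMMA
        v01, degen = _minmax_in_fov(v01, fov)
    out = (2.0 * v01 - 1.0) if not degen else np.zeros_like(v01)
    out = np.where(fov, out, BACKGROUND_FILL).astype(np.float32)
    return PreprocessedImage(values=out, fov=fov.copy(), scale_factor=1)


def erode_fov(fov: np.ndarray, margin: int = FOV_EROSION_MARGIN) -> np.ndarray:
    """Erode a binary mask inward by ``margin`` pixels (3x3 square element)."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    fov = np.asarray(fov).astype(bool)
    if margin == 0:
        return fov.copy()
    return ndi.binary_erosion(fov, structure=np.ones((3, 3), bool),
                              iterations=margin)


def resample_image(image: np.ndarray, factor: int, *, order: int = 1) -> np.ndarray:
    """Bilinear down-sampling by an integer factor (order=0 for masks)."""
    if factor < 1:
        raise ValueError("resample factor must be >= 1")
    if factor == 1:
        return np.asarray(image).copy()
    h, w = image.shape[:2]
    out_shape = (max(1, round(h / factor)), max(1, round(w / factor)))
    out = transform.resize(image.astype(float), out_shape, order=order,
                           anti_aliasing=False, preserve_range=True)
    if image.dtype == bool:
        return out > 0.5
    return out.astype(np.float32)


def resample_pair(pre: PreprocessedImage, factor: int) -> PreprocessedImage:
    """Down-sample a preprocessed image together with its FOV mask."""
    values = resample_image(pre.values, factor, order=1)
    fov = resample_image(pre.fov, factor, order=0)
    return PreprocessedImage(values=values, fov=fov,
                             scale_factor=pre.scale_factor * factor)


def restore_prediction(pred: np.ndarray, original_shape: tuple[int, int]) -> np.ndarray:
    """Bilinearly up-scale a probability map back to the annotation's shape."""
    if tuple(pred.shape) == tuple(original_shape):
        return np.asarray(pred, dtype=np.float32).copy()
    out = transform.resize(np.asarray(pred, dtype=float), original_shape,
                           order=1, anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)
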