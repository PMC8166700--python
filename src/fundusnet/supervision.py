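"""Training objective: diameter-based weight maps, weighted focal loss,
l2 regularization and the learning-rate staircase.

Thin vessels contribute few pixels, so the per-pixel loss is multiplied by
an inverse-diameter weight

    W(x) = 1                      on background,
    W(x) = max(1, 1/(0.18 * d_x)) on vessel pixels,

where ``d_x`` is the vessel diameter at pixel ``x`` in the label map.  The
weight saturates at 1 for calibers >= 1/0.18 ~ 5.56 px, so only thin
vessels are up-weighted.  Diameters are estimated as twice the Euclidean
distance-transform value at the nearest medial-axis pixel, which keeps the
edge pixels of a thick vessel from being spuriously up-weighted.

The segmentation term is a class-balanced focal loss (focusing factor
gamma, foreground balance alpha), averaged over the batch pixels and summed
with an l2 penalty over the convolution kernels:

    L = (1/N) * sum_i focal(x_i) * W(x_i) + lambda * L_l2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import medial_axis

__all__ = [
    "WeightMap",
    "LossConfig",
    "WEIGHT_DIAMETER_SCALE",
    "diameter_map",
    "weight_at",
    "weight_map",
    "focal_term",
    "l2_penalty",
    "total_loss",
    "lr_at",
]

WEIGHT_DIAMETER_SCALE = 0.18
LR_DECAY = 0.9
LR_DECAY_PERIOD = 10_000
PROB_FLOOR = 1e-7


@dataclass
class LossConfig:
    """Focal-loss and regularization factors.

    ``l2_mode`` selects the regularizer normalization: ``"mean"`` penalizes
    0.5 * mean(w^2) (the training default — at lambda = 0.2 a sum-type
    penalty overwhelms the pixel loss for any non-trivial model), ``"sum"``
    penalizes 0.5 * sum(w^2).
    """

    gamma: float = 2.0
    alpha: float = 0.9
    lambda_reg: float = 0.2
    l2_mode: str = "mean"

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.l2_mode not in ("mean", "sum"):
            raise ValueError("l2_mode must be 'mean' or 'sum'")


@dataclass
class WeightMap:
    """Per-pixel loss weights W >= 1 with the diameter field they came from."""

    W: np.ndarray
    d: np.ndarray


SKELETON_SMOOTHING_WINDOW = 5


def diameter_map(annotation: np.ndarray) -> np.ndarray:
    """Per-pixel vessel diameter (px) on the foreground; NaN on background.

    The diameter at a vessel pixel is twice the distance-transform value at
    its nearest skeleton (medial-axis) pixel, i.e. the local caliber of the
    vessel the pixel belongs to.  Skeleton radii are averaged over a small
    window along the skeleton to suppress pixel-grid quantization noise; an
    isolated pixel keeps its exact value (diameter 2).
    """
    mask = np.asarray(annotation).astype(bool)
    out = np.full(mask.shape, np.nan, dtype=np.float32)
    if not mask.any():
        return out
    skel, dist = medial_axis(mask, return_distance=True)
    if not skel.any():  # pathological; fall back to the local caliber
        out[mask] = 2.0 * dist[mask]
        return out
    w = SKELETON_SMOOTHING_WINDOW
    kernel = np.ones((w, w))
    num = ndi.convolve(np.where(skel, dist, 0.0), kernel, mode="constant")
    den = ndi.convolve(skel.astype(float), kernel, mode="constant")
    radius = np.where(skel, num / np.maximum(den, 1e-9), 0.0)
    _, idx = ndi.distance_transform_edt(~skel, return_indices=True)
    out[mask] = 2.0 * radius[idx[0], idx[1]][mask]
    return out


def weight_at(d, is_foreground):
    """Loss weight of one pixel (or arrays): background 1, foreground
    max(1, 1/(0.18*d))."""
    d = np.asarray(d, dtype=float)
    fg = np.asarray(is_foreground, dtype=bool)
    if np.any(fg & ~(d > 0)):
        raise ValueError("foreground diameter must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.maximum(1.0, 1.0 / (WEIGHT_DIAMETER_SCALE * d))
    out = np.where(fg, w, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def weight_map(annotation: np.ndarray,
               diameters: np.ndarray | None = None) -> WeightMap:
    """Build the per-pixel weight map of a binary vessel annotation.

    ``diameters`` may supply a known caliber field (synthetic ground truth);
    otherwise diameters are estimated from the annotation's medial axis.
    """
    mask = np.asarray(annotation).astype(bool)
    d = diameter_map(mask) if diameters is None else np.asarray(diameters, float)
    W = np.ones(mask.shape, dtype=np.float32)
    if mask.any():
        W[mask] = weight_at(d[mask], True)
    if not np.all(np.isfinite(W)):
        raise ValueError("weight map contains non-finite values")
    return WeightMap(W=W, d=d)


def focal_term(p_true, is_foreground, cfg: LossConfig):
    """Class-balanced focal loss of pixels given the probability assigned to
    their true class: -alpha_c * (1-p)^gamma * log(p)."""
    p = np.clip(np.asarray(p_true, dtype=float), PROB_FLOOR, 1.0)
    fg = np.asarray(is_foreground, dtype=bool)
    a = np.where(fg, cfg.alpha, 1.0 - cfg.alpha)
    out = -a * (1.0 - p) ** cfg.gamma * np.log(p)
    if out.ndim == 0:
        return float(out)
    return out


def focal_grad(p_true, is_foreground, cfg: LossConfig):
    """d(focal_term)/d(p_true); zero where the probability floor clips."""
    p = np.asarray(p_true, dtype=float)
    fg = np.asarray(is_foreground, dtype=bool)
    a = np.where(fg, cfg.alpha, 1.0 - cfg.alpha)
    pc = np.clip(p, PROB_FLOOR, 1.0 - 1e-12)
    focus = 0.0
    if cfg.gamma > 0:
        focus = cfg.gamma * (1.0 - pc) ** (cfg.gamma - 1.0) * np.log(pc)
    g = a * (focus - (1.0 - pc) ** cfg.gamma / pc)
    return np.where(p <= PROB_FLOOR, 0.0, g)


def l2_penalty(kernel_weights, mode: str = "mean") -> float:
    """0.5 * sum(w^2) over all kernel arrays ('sum'), or divided by the
    total weight count ('mean')."""
    arrays = [np.asarray(w) for w in kernel_weights]
    ssq = sum(float((w ** 2).sum()) for w in arrays)
    if mode == "sum":
        return 0.5 * ssq
    n = sum(w.size for w in arrays)
    return 0.5 * ssq / max(n, 1)


def total_loss(probabilities: np.ndarray, labels: np.ndarray,
               weights: np.ndarray, kernel_weights, cfg: LossConfig,
               side_outputs=None) -> float:
    """Full training objective for one batch.

    Parameters
    ----------
    probabilities : (..., 2, H, W) softmax maps (batch axis optional).
    labels : binary maps, same spatial shape.
    weights : per-pixel loss weights, same spatial shape.
    kernel_weights : iterable of kernel arrays entering the l2 penalty.
    side_outputs : optional list of side-branch maps (2 channels, input
        shape); each contributes a mean-square-error term against the
        one-hot label map.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim == 3:
        p = p[None]
    y = np.asarray(labels).astype(bool)
    if y.ndim == 2:
        y = y[None]
    w = np.asarray(weights, dtype=float)
    if w.ndim == 2:
        w = w[None]
    if cfg.lambda_reg < 0:
        raise ValueError("lambda_reg must be >= 0")
    if p.shape[0] != y.shape[0] or p.shape[2:] != y.shape[1:] or y.shape != w.shape:
        raise ValueError("probability/label/weight shapes disagree")
    p_true = np.where(y, p[:, 1], p[:, 0])
    seg = float(np.mean(focal_term(p_true, y, cfg) * w))
    reg = cfg.lambda_reg * l2_penalty(kernel_weights, cfg.l2_mode)
    side = 0.0
    if side_outputs:
        onehot = np.stack([(~y).astype(float), y.astype(float)], axis=1)
        for s in side_outputs:
            s = np.asarray(s, dtype=float)
            if s.ndim == 3:
                s = s[None]
            side += float(np.mean((s - onehot) ** 2))
    return seg + reg + side


def lr_at(iteration: int, lr0: float) -> float:
    """Learning-rate staircase: lr0 * 0.9**floor(iteration / 10000)."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return lr0 * LR_DECAY ** (iteration // LR_DECAY_PERIOD)
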