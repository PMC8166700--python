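"""Database protocol: registry constants, split schemes, patch sampling,
augmentation, and the training-set-reduction experiment.

The four public fundus databases are described by fixed constants (image
counts and shapes, resampling factors, patch and minibatch sizes, split
scheme).  DRIVE uses its fixed half/half train–test division with four
training images set aside for validation; the other databases use a seeded
fourfold cross-validation whose test partitions are disjoint and jointly
cover every image.

A database on disk is a directory with ``images/``, ``fov/`` and
``labels/`` rasters (optionally ``diameters/`` float TIFFs for synthetic
data) plus a ``manifest.csv`` listing the image identifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import measure, transform

from .preprocessing import FundusSample, preprocess, resample_pair
from .supervision import weight_map

__all__ = [
    "DatasetSpec",
    "SplitPlan",
    "REGISTRY",
    "AugmentParams",
    "make_splits",
    "reduce_training_set",
    "sample_batch",
    "augment",
    "apply_augmentation",
    "draw_augment_params",
    "load_database",
    "save_database",
    "fov_fallback",
    "prepare_samples",
    "synthetic_dataset_spec",
]


@dataclass(frozen=True)
class DatasetSpec:
    """Constants of one database's training/evaluation protocol."""

    name: str
    n_images: int
    image_shape: tuple[int, int]   # (rows, cols)
    resample_factor: int
    patch_size: int
    batch_size: int
    split_scheme: str              # 'fixed_drive' | 'fourfold'
    val_size: int = 4


REGISTRY: dict[str, DatasetSpec] = {
    "drive": DatasetSpec("drive", 40, (584, 565), 1, 168, 50, "fixed_drive", 4),
    "stare": DatasetSpec("stare", 20, (605, 700), 1, 168, 50, "fourfold", 4),
    "hrf": DatasetSpec("hrf", 45, (2336, 3504), 4, 400, 15, "fourfold", 7),
    "chase_db1": DatasetSpec("chase_db1", 28, (960, 999), 2, 200, 40, "fourfold", 4),
}


def synthetic_dataset_spec(n_images: int, image_size: int = 512,
                           patch_size: int = 96, batch_size: int = 8,
                           name: str = "synthetic",
                           split_scheme: str = "fourfold") -> DatasetSpec:
    """Protocol constants for a synthetic phantom database."""
    return DatasetSpec(name, n_images, (image_size, image_size), 1,
                       patch_size, batch_size, split_scheme, 4)


@dataclass
class SplitPlan:
    fold: int
    train: list[str]
    validation: list[str]
    test: list[str]

    def __post_init__(self):
        sets = [set(self.train), set(self.validation), set(self.test)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("split lists are not disjoint")


def _default_ids(n: int) -> list[str]:
    return [f"{i + 1:02d}" for i in range(n)]


def make_splits(db: DatasetSpec, fold: int, seed: int,
                ids: list[str] | None = None) -> SplitPlan:
    """Seeded deterministic train/validation/test partition of a database.

    DRIVE: the sorted first half is the fixed test set, the second half the
    training set, from which ``val_size`` images move to validation.
    Fourfold databases: a seeded permutation is cut into four test
    partitions (disjoint across folds, covering every image); the remainder
    splits into validation (``val_size``) and training.
    """
    ids = sorted(ids) if ids is not None else _default_ids(db.n_images)
    if len(ids) != db.n_images:
        raise ValueError(f"{db.name} expects {db.n_images} ids, got {len(ids)}")
    rng = np.random.default_rng(seed)
    if db.split_scheme == "fixed_drive":
        if fold != 0:
            raise ValueError("DRIVE has a single fixed split (fold 0)")
        half = len(ids) // 2
        test = ids[:half]
        trainval = ids[half:]
        val_idx = set(rng.choice(len(trainval), size=db.val_size, replace=False))
        validation = [x for i, x in enumerate(trainval) if i in val_idx]
        train = [x for i, x in enumerate(trainval) if i not in val_idx]
        return SplitPlan(fold, train, validation, test)
    if db.split_scheme != "fourfold":
        raise ValueError(f"unknown split scheme '{db.split_scheme}'")
    if not 0 <= fold <= 3:
        raise ValueError("fold must lie in 0..3")
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    base, extra = divmod(n, 4)
    sizes = [base + (1 if k < extra else 0) for k in range(4)]
    starts = np.cumsum([0] + sizes)
    test = perm[starts[fold]:starts[fold + 1]]
    rest = [x for x in perm if x not in set(test)]
    validation = rest[:db.val_size]
    train = rest[db.val_size:]
    return SplitPlan(fold, train, validation, test)


def reduce_training_set(plan: SplitPlan, n_keep: int, seed: int) -> SplitPlan:
    """Keep a seeded random subset of the training images (the training-set
    reduction experiment); validation and test are unchanged."""
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if n_keep > len(plan.train):
        raise ValueError("n_keep exceeds the training-set size")
    if n_keep == len(plan.train):
        return SplitPlan(plan.fold, list(plan.train), list(plan.validation),
                         list(plan.test))
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(len(plan.train), size=n_keep, replace=False))
    train = [x for i, x in enumerate(plan.train) if i in keep]
    return SplitPlan(plan.fold, train, list(plan.validation), list(plan.test))


# ---------------------------------------------------------------------------
# patch sampling and augmentation
# ---------------------------------------------------------------------------

def sample_batch(images, labels, weight_maps, db: DatasetSpec,
                 rng: np.random.Generator | int):
    """One seeded minibatch of fully-inside patches.

    Returns ``(x, y, w)`` with shapes ``(B, 1, P, P)``, ``(B, P, P)``,
    ``(B, P, P)``; the label and weight patches are cut at identical
    positions, and top-left corners are uniform over all admissible
    positions.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    p, b = db.patch_size, db.batch_size
    x = np.empty((b, 1, p, p), dtype=np.float32)
    y = np.empty((b, p, p), dtype=bool)
    w = np.empty((b, p, p), dtype=np.float32)
    n_img = len(images)
    for k in range(b):
        i = int(rng.integers(n_img))
        h, wd = images[i].shape
        if p > h or p > wd:
            raise ValueError(f"patch size {p} exceeds image shape {(h, wd)}")
        top = int(rng.integers(h - p + 1))
        left = int(rng.integers(wd - p + 1))
        x[k, 0] = images[i][top:top + p, left:left + p]
        y[k] = labels[i][top:top + p, left:left + p]
        w[k] = weight_maps[i][top:top + p, left:left + p]
    return x, y, w


@dataclass
class AugmentParams:
    """One draw of the affine + photometric augmentation magnitudes."""

    rotation_deg: float = 0.0
    shear: float = 0.0
    zoom: float = 1.0
    noise_sigma: float = 0.0
    intensity_shift: float = 0.0


# Augmentation magnitudes: rotation within 20 degrees, shearing within 30%
# and zoom within 50-150% of the linear patch size, uniform intensity shift
# within 8% of the intensity range ([-1, 1] spans 2.0).  The additive noise
# magnitude is unspecified in the protocol; 2% of the range is used.
ROTATION_MAX_DEG = 20.0
SHEAR_MAX = 0.30
ZOOM_RANGE = (0.5, 1.5)
INTENSITY_SHIFT_MAX = 0.08
NOISE_SIGMA_FRAC = 0.02
INTENSITY_RANGE = 2.0
FILL_IMAGE = -1.0
FILL_LABEL = 0.0
FILL_WEIGHT = 1.0


def draw_augment_params(rng: np.random.Generator) -> AugmentParams:
    return AugmentParams(
        rotation_deg=float(rng.uniform(-ROTATION_MAX_DEG, ROTATION_MAX_DEG)),
        shear=float(rng.uniform(-SHEAR_MAX, SHEAR_MAX)),
        zoom=float(rng.uniform(*ZOOM_RANGE)),
        noise_sigma=NOISE_SIGMA_FRAC * INTENSITY_RANGE,
        intensity_shift=float(rng.uniform(-INTENSITY_SHIFT_MAX,
                                          INTENSITY_SHIFT_MAX)) * INTENSITY_RANGE,
    )


def _affine_matrix(params: AugmentParams, size: int) -> np.ndarray:
    """Output->input (inverse) map of the centered rotation/shear/zoom."""
    c = (size - 1) / 2.0
    th = math.radians(params.rotation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    shear = np.array([[1.0, params.shear], [0.0, 1.0]])
    M = params.zoom * rot @ shear
    Minv = np.linalg.inv(M)
    A = np.eye(3)
    A[:2, :2] = Minv
    A[:2, 2] = [c, c] - Minv @ np.array([c, c])
    return A


def apply_augmentation(patch: np.ndarray, label: np.ndarray,
                       weight: np.ndarray, params: AugmentParams,
                       rng: np.random.Generator | None = None):
    """Apply one augmentation draw; shape-preserving.

    The image patch is warped bilinearly (out-of-bounds filled with the
    background value -1); label and weight patches use nearest-neighbour
    interpolation so labels stay strictly binary.  Photometric noise and the
    intensity shift apply to the image only.
    """
    size = patch.shape[0]
    A = _affine_matrix(params, size)
    tf = transform.AffineTransform(matrix=A)
    img = transform.warp(patch.astype(float), tf, order=1, cval=FILL_IMAGE,
                         preserve_range=True, mode="constant")
    lab = transform.warp(label.astype(float), tf, order=0, cval=FILL_LABEL,
                         preserve_range=True, mode="constant") > 0.5
    wgt = transform.warp(weight.astype(float), tf, order=0, cval=FILL_WEIGHT,
                         preserve_range=True, mode="constant")
    if params.noise_sigma > 0 and rng is not None:
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    img = img + params.intensity_shift
    return img.astype(np.float32), lab, wgt.astype(np.float32)


def augment(patch: np.ndarray, label: np.ndarray, weight: np.ndarray,
            rng: np.random.Generator | int):
    """One seeded augmentation draw applied to a patch triple."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    return apply_augmentation(patch, label, weight, draw_augment_params(rng), rng)


# ---------------------------------------------------------------------------
# disk layout
# ---------------------------------------------------------------------------

def save_database(samples, directory) -> Path:
    """Write samples in the standard layout (images/fov/labels + manifest)."""
    root = Path(directory)
    for sub in ("images", "fov", "labels"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    has_diam = any(s.diameter_map is not None for s in samples)
    if has_diam:
        (root / "diameters").mkdir(exist_ok=True)
    rows = []
    for s in samples:
        iio.imwrite(root / "images" / f"{s.image_id}.png", s.rgb)
        iio.imwrite(root / "fov" / f"{s.image_id}.png",
                    (s.fov.astype(np.uint8) * 255))
        if s.annotation is not None:
            iio.imwrite(root / "labels" / f"{s.image_id}.png",
                        (s.annotation.astype(np.uint8) * 255))
        if s.diameter_map is not None:
            d = np.nan_to_num(s.diameter_map, nan=0.0).astype(np.float32)
            tifffile.imwrite(root / "diameters" / f"{s.image_id}.tif", d)
        rows.append({"id": s.image_id, "db_tag": s.db_tag})
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    return root


def load_database(directory) -> list[FundusSample]:
    """Read a database directory written by :func:`save_database` (or laid
    out the same way by hand)."""
    root = Path(directory)
    manifest = pd.read_csv(root / "manifest.csv", dtype={"id": str})
    samples = []
    for _, row in manifest.iterrows():
        sid = str(row["id"])
        rgb = np.asarray(iio.imread(root / "images" / f"{sid}.png"))[..., :3]
        fov = np.asarray(iio.imread(root / "fov" / f"{sid}.png")) > 127
        label_path = root / "labels" / f"{sid}.png"
        ann = (np.asarray(iio.imread(label_path)) > 127) if label_path.exists() else None
        diam = None
        dpath = root / "diameters" / f"{sid}.tif"
        if dpath.exists():
            diam = tifffile.imread(dpath).astype(np.float32)
            diam[diam <= 0] = np.nan
        samples.append(FundusSample(rgb=rgb, fov=fov, annotation=ann,
                                    diameter_map=diam,
                                    db_tag=str(row.get("db_tag", "")),
                                    image_id=sid))
    return samples


def fov_fallback(rgb: np.ndarray, threshold_frac: float = 0.12) -> np.ndarray:
    """Threshold-based FOV mask for databases shipping none: luminance
    threshold, largest connected component, filled holes."""
    lum = np.asarray(rgb, dtype=float).mean(axis=2)
    mask = lum > threshold_frac * max(lum.max(), 1e-9)
    lab = measure.label(mask)
    if lab.max() == 0:
        raise ValueError("no foreground found for FOV fallback")
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return ndi.binary_fill_holes(lab == largest)


def prepare_samples(samples, db: DatasetSpec) -> dict:
    """Preprocess samples and build their label/weight grids at network
    resolution; returns ``{image_id: (values, label, weights)}``.

    Labels and weight maps are computed at annotation resolution; for
    resampled databases both are down-sampled with nearest-neighbour
    interpolation alongside the image.
    """
    prepared = {}
    for s in samples:
        pre = preprocess(s)
        if s.annotation is None:
            raise ValueError(f"sample {s.image_id} has no annotation")
        wm = weight_map(s.annotation, diameters=s.diameter_map)
        label = s.annotation
        weights = wm.W
        if db.resample_factor > 1:
            pre = resample_pair(pre, db.resample_factor)
            f = db.resample_factor
            out_shape = pre.values.shape
            label = transform.resize(label.astype(float), out_shape, order=0,
                                     anti_aliasing=False,
                                     preserve_range=True) > 0.5
            weights = transform.resize(weights, out_shape, order=0,
                                       anti_aliasing=False,
                                       preserve_range=True).astype(np.float32)
        prepared[s.image_id] = (pre.values, label, weights)
    return prepared
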