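"""Synthetic fundus phantoms with exact vessel masks and caliber maps.

A phantom emulates the properties of a fundus photograph that matter to the
pipeline: a circular field of view on a dark surround, a branching
curvilinear vessel tree that is darker than a smoothly illuminated noisy
background (contrast strongest in the green channel), vessel calibers from
about 1 to about 10 px, and a vessel pixel fraction around 8-15% of the
FOV.  Vessels are rendered by stamping discs along random-walk polylines,
which keeps the per-pixel ground-truth diameter exact on the binary mask —
no anti-aliasing blurs the caliber bookkeeping.

Two presets are provided: preset A (the default conditions) and preset B, a
second "database" with different illumination and vessel contrast, used by
the cross-database transfer harness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.draw import disk

from .data_pipeline import save_database
from .preprocessing import FundusSample

__all__ = [
    "PhantomConfig",
    "preset_a",
    "preset_b",
    "generate_tree",
    "render",
    "generate_phantom",
    "make_dataset",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Conditions of one synthetic database.

    Calibers are in pixels; ``contrast_depth`` is the relative darkening of
    the green channel on vessels; ``illumination_gradient`` the relative
    radial fall-off of the background; ``noise_sigma`` the additive Gaussian
    noise on the 8-bit scale.
    """

    image_size: int = 512
    fov_radius_frac: float = 0.46
    n_root_vessels: int = 7
    caliber_range: tuple[float, float] = (1.5, 9.0)
    branch_prob: float = 0.10
    contrast_depth: float = 0.35
    illumination_gradient: float = 0.30
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self):
        d_min, d_max = self.caliber_range
        if d_min < 1:
            raise ValueError("minimum caliber must be >= 1 px")
        if d_max < d_min:
            raise ValueError("caliber range must be ordered")
        for frac in (self.fov_radius_frac, self.branch_prob,
                     self.contrast_depth):
            if not 0 < frac <= 1:
                raise ValueError("fractions must lie in (0, 1]")
        if self.n_root_vessels < 1:
            raise ValueError("need at least one root vessel")


def preset_a(**overrides) -> PhantomConfig:
    """Default synthetic conditions (database 'A')."""
    return replace(PhantomConfig(), **overrides)


def preset_b(**overrides) -> PhantomConfig:
    """A second synthetic database with brighter-falling illumination and
    weaker vessel contrast, for transfer experiments."""
    base = PhantomConfig(fov_radius_frac=0.44, contrast_depth=0.25,
                         illumination_gradient=0.45, noise_sigma=10.0)
    return replace(base, **overrides)


def generate_tree(cfg: PhantomConfig):
    """Seeded branching random walks stamped as discs.

    Returns ``(mask, diameter_map)``: the binary vessel mask and, on vessel
    pixels, the rendering caliber (larger vessels win at crossings);
    background pixels are NaN.
    """
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size
    d_min, d_max = cfg.caliber_range
    center = (size - 1) / 2.0
    R = cfg.fov_radius_frac * size

    diam = np.zeros((size, size), dtype=np.float32)
    step = 2.0
    taper = 0.985          # per-step decay of the excess caliber over d_min
    tip = 0.05 * (d_max - d_min)  # walkers die when this thin
    max_steps = int(2.0 * R / step)

    walkers = []
    for k in range(cfg.n_root_vessels):
        ang = 2 * np.pi * (k + rng.uniform(-0.2, 0.2)) / cfg.n_root_vessels
        pos = np.array([center + 0.92 * R * np.sin(ang),
                        center + 0.92 * R * np.cos(ang)])
        inward = np.arctan2(center - pos[0], center - pos[1])
        heading = inward + rng.uniform(-0.5, 0.5)
        cal = d_min + rng.uniform(0.6, 1.0) * (d_max - d_min)
        walkers.append((pos, heading, cal, max_steps))

    while walkers:
        pos, heading, cal, budget = walkers.pop()
        pos = pos.copy()
        for _ in range(budget):
            r, c = pos
            if (r - center) ** 2 + (c - center) ** 2 > (0.97 * R) ** 2:
                break
            # stamp radius calibrated so the rendered band's medial-axis
            # diameter matches the nominal caliber on the pixel grid
            rr, cc = disk((r, c), max(cal / 2.0 - 0.3, 0.71), shape=diam.shape)
            diam[rr, cc] = np.maximum(diam[rr, cc], cal)
            heading += rng.normal(0.0, 0.18)
            pos[0] += step * np.sin(heading)
            pos[1] += step * np.cos(heading)
            # monotone taper toward (never below) the minimum caliber
            cal = d_min + (cal - d_min) * taper
            if cal - d_min < tip and d_max > d_min:
                break
            if rng.uniform() < cfg.branch_prob:
                child_cal = d_min + (cal - d_min) * rng.uniform(0.4, 0.8)
                turn = rng.uniform(0.35, 0.9) * rng.choice([-1.0, 1.0])
                walkers.append((pos.copy(), heading + turn, child_cal,
                                int(budget * rng.uniform(0.3, 0.6))))
                cal = d_min + (cal - d_min) * rng.uniform(0.85, 0.97)

    mask = diam > 0
    out = np.where(mask, diam, np.nan).astype(np.float32)
    return mask, out


def render(mask: np.ndarray, cfg: PhantomConfig,
           diameters: np.ndarray | None = None) -> FundusSample:
    """Render a vessel mask as an 8-bit RGB fundus phantom.

    The background is a radially falling illumination field plus Gaussian
    noise; vessels darken the green channel most (red/blue less), the
    surround outside the circular FOV is near-black.
    """
    rng = np.random.default_rng([cfg.seed, 9151])
    size = cfg.image_size
    center = (size - 1) / 2.0
    R = cfg.fov_radius_frac * size
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = ((yy - center) ** 2 + (xx - center) ** 2) / R ** 2
    fov = r2 <= 1.0
    illum = 1.0 - cfg.illumination_gradient * r2

    base = {"r": 185.0, "g": 150.0, "b": 45.0}
    vessel_drop = {"r": 0.5 * cfg.contrast_depth,
                   "g": cfg.contrast_depth,
                   "b": 0.3 * cfg.contrast_depth}
    channels = []
    for ch in ("r", "g", "b"):
        img = base[ch] * illum
        img = np.where(mask, img * (1.0 - vessel_drop[ch]), img)
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
        img = np.where(fov, img, 4.0)
        channels.append(np.clip(img, 0, 255))
    rgb = np.stack(channels, axis=-1).astype(np.uint8)
    return FundusSample(rgb=rgb, fov=fov, annotation=mask,
                        diameter_map=diameters, db_tag="synthetic")


def generate_phantom(cfg: PhantomConfig, image_id: str = "01") -> FundusSample:
    """Generate one phantom (tree + rendering) from a config."""
    mask, diam = generate_tree(cfg)
    sample = render(mask, cfg, diameters=diam)
    sample.image_id = image_id
    return sample


def make_dataset(n_images: int, cfg: PhantomConfig, seed: int,
                 directory) -> Path:
    """Write ``n_images`` phantoms as a database directory in the standard
    layout; per-image child seeds derive deterministically from ``seed``."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    child_seeds = np.random.default_rng(seed).integers(2 ** 31, size=n_images)
    samples = []
    for i, cs in enumerate(child_seeds):
        c = replace(cfg, seed=int(cs))
        samples.append(generate_phantom(c, image_id=f"{i + 1:02d}"))
    return save_database(samples, directory)
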