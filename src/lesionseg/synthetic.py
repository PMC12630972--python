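"""Seeded synthetic dermoscopic-like scenes with exact ground truth.

Each scene is a skin-tone background with smooth illumination and pixel
noise, one irregular darker lesion (an ellipse whose radius is modulated by
a low-order harmonic series), and optionally thin dark hair strands drawn
across the frame.  The generator's job is to exercise the preprocessing
constants in their intended regime: strands are thin (width <= 3 px) and
dark (default 80 intensity units below their surroundings), so a 17x17
black-hat response exceeds the detection threshold of 50 on strand pixels;
lesions have controllable contrast including a low-contrast mode.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = ["LesionSpec", "HairSpec", "gen_background", "gen_lesion_mask",
           "render_scene", "generate_arrays", "generate_dataset",
           "sample_lesion_spec"]

_SKIN_BASE = np.array([205.0, 160.0, 135.0])  # light skin tone, RGB


@dataclass(frozen=True)
class LesionSpec:
    center: tuple            # (row, col) in pixels
    a: float                 # semi-axis, columns
    b: float                 # semi-axis, rows
    irregularity: float = 0.2    # radial boundary perturbation amplitude
    contrast: float = 60.0       # mean intensity drop inside the lesion
    texture_sigma: float = 5.0   # intra-lesion noise, intensity units

    def __post_init__(self):
        if self.a < 4 or self.b < 4:
            raise ValueError("lesion semi-axes must be >= 4 px")
        if not 0 <= self.irregularity <= 0.5:
            raise ValueError("irregularity must lie in [0, 0.5]")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")


@dataclass(frozen=True)
class HairSpec:
    n_strands: int = 3
    width: int = 2               # 1-3 px
    darkness: float = 80.0       # intensity drop vs. surroundings
    curvature: float = 0.25      # control-point jitter as fraction of frame

    def __post_init__(self):
        if not 1 <= self.width <= 3:
            raise ValueError("strand width must be 1-3 px")
        if self.darkness <= 50:
            raise ValueError("strand darkness must exceed the detection "
                             "threshold (50) for the black-hat contract")
        if self.n_strands < 0:
            raise ValueError("n_strands must be nonnegative")


def gen_background(h: int, w: int, seed: int, noise_sigma: float = 4.0,
                   gradient: bool = True) -> np.ndarray:
    """Skin-tone background: base colour + smooth illumination + noise."""
    if h < 64 or w < 64:
        raise ValueError("background must be at least 64 x 64")
    rng = np.random.default_rng(seed)
    base = _SKIN_BASE + rng.uniform(-12, 12, 3)
    img = np.broadcast_to(base, (h, w, 3)).astype(np.float64).copy()
    if gradient:
        yy, xx = np.mgrid[0:h, 0:w]
        direction = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(5, 15)
        ramp = (np.cos(direction) * xx / w + np.sin(direction) * yy / h)
        img += (amp * ramp)[..., None]
    if noise_sigma > 0:
        img += rng.normal(0, noise_sigma, (h, w, 3))
    return np.clip(img, 0, 255).astype(np.uint8)


def gen_lesion_mask(h: int, w: int, spec: LesionSpec, seed: int) -> np.ndarray:
    """Rasterize one irregular lesion as a {0,1} mask.

    The boundary is an ellipse whose radius is modulated by harmonics of
    order 2-5 with total amplitude ``irregularity``; that keeps the region
    star-shaped about the centre, hence a single 4-connected component.
    """
    cy, cx = spec.center
    margin = 1.0 + spec.irregularity
    if (cy - spec.b * margin < 1 or cy + spec.b * margin > h - 2
            or cx - spec.a * margin < 1 or cx + spec.a * margin > w - 2):
        raise ValueError("lesion does not fit in the frame with margin")
    rng = np.random.default_rng(seed)
    orders = np.arange(2, 6)
    amps = rng.uniform(0.2, 1.0, orders.size)
    if spec.irregularity > 0:
        amps *= spec.irregularity / amps.sum()
    else:
        amps[:] = 0.0
    phases = rng.uniform(0, 2 * np.pi, orders.size)

    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx - cx) / spec.a
    v = (yy - cy) / spec.b
    rad = np.hypot(u, v)
    theta = np.arctan2(v, u)
    boundary = 1.0 + sum(a * np.cos(m * theta + p)
                         for a, m, p in zip(amps, orders, phases))
    return (rad <= boundary).astype(np.uint8)


def _draw_strand(h: int, w: int, rng: np.random.Generator,
                 curvature: float) -> np.ndarray:
    """One quadratic-Bezier strand crossing the frame, 1 px wide."""
    if rng.random() < 0.5:   # left-right
        p0 = np.array([rng.uniform(0, h - 1), 0.0])
        p2 = np.array([rng.uniform(0, h - 1), w - 1.0])
    else:                    # top-bottom
        p0 = np.array([0.0, rng.uniform(0, w - 1)])
        p2 = np.array([h - 1.0, rng.uniform(0, w - 1)])
    mid = (p0 + p2) / 2
    p1 = mid + rng.uniform(-curvature, curvature, 2) * np.array([h, w])
    t = np.linspace(0, 1, 4 * (h + w))[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
    ys = np.clip(np.rint(pts[:, 0]).astype(int), 0, h - 1)
    xs = np.clip(np.rint(pts[:, 1]).astype(int), 0, w - 1)
    strand = np.zeros((h, w), dtype=bool)
    strand[ys, xs] = True
    return strand


_WIDTH_FOOTPRINT = {
    1: None,
    2: np.array([[1, 1], [1, 1]], dtype=bool),
    3: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


def render_scene(background: np.ndarray, mask: np.ndarray, spec: LesionSpec,
                 hair: Optional[HairSpec] = None, seed: int = 0):
    """Compose lesion (and optional hairs) onto a background.

    The lesion region is darkened by ``contrast`` with a 2 px feathered
    border and intra-lesion texture noise; hairs are dark curves drawn over
    the whole frame.  Returns (image uint8, hair_truth {0,1} uint8).  The
    hair-free reference for the same seed is the call with ``hair=None``.
    """
    background = np.asarray(background)
    mask = np.asarray(mask)
    if mask.shape != background.shape[:2]:
        raise ValueError("background and mask are not aligned")
    lesion_seed, hair_seed = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(lesion_seed)

    img = background.astype(np.float64).copy()
    inside = mask > 0
    if inside.any():
        depth = ndimage.distance_transform_edt(inside)
        alpha = np.clip(depth / 2.0, 0.0, 1.0)        # 2 px feather
        img -= (spec.contrast * alpha)[..., None]
        if spec.texture_sigma > 0:
            noise = rng.normal(0, spec.texture_sigma, mask.shape)
            img += (noise * alpha)[..., None]

    h, w = mask.shape
    hair_truth = np.zeros((h, w), dtype=np.uint8)
    if hair is not None and hair.n_strands > 0:
        hrng = np.random.default_rng(hair_seed)
        strands = np.zeros((h, w), dtype=bool)
        for _ in range(hair.n_strands):
            strands |= _draw_strand(h, w, hrng, hair.curvature)
        fp = _WIDTH_FOOTPRINT[hair.width]
        if fp is not None:
            strands = ndimage.binary_dilation(strands, structure=fp)
        img[strands] -= hair.darkness
        hair_truth = strands.astype(np.uint8)

    return np.clip(img, 0, 255).astype(np.uint8), hair_truth


def sample_lesion_spec(h: int, w: int, rng: np.random.Generator,
                       low_contrast: bool = False) -> LesionSpec:
    """Draw a random lesion specification that fits the frame."""
    a = rng.uniform(0.14, 0.26) * w
    b = rng.uniform(0.14, 0.26) * h
    rho = rng.uniform(0.1, 0.3)
    margin = 1.0 + rho
    cy = rng.uniform(b * margin + 2, h - b * margin - 3)
    cx = rng.uniform(a * margin + 2, w - a * margin - 3)
    contrast = (rng.uniform(15, 30) if low_contrast
                else rng.uniform(50, 75))
    return LesionSpec(center=(cy, cx), a=a, b=b, irregularity=rho,
                      contrast=contrast, texture_sigma=rng.uniform(3, 7))


def generate_arrays(n: int, size: int = 256, seed: int = 0,
                    hair: Optional[HairSpec] = None,
                    low_contrast_frac: float = 0.3):
    """In-memory dataset: (images uint8 (n,size,size,3), masks {0,1} (n,size,size),
    hair_truths {0,1}).  A ``low_contrast_frac`` fraction of scenes uses a
    reduced lesion contrast of 15-30 intensity units."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n + 1)
    pick_rng = np.random.default_rng(child_seeds[-1])
    low = pick_rng.random(n) < low_contrast_frac
    images = np.empty((n, size, size, 3), dtype=np.uint8)
    masks = np.empty((n, size, size), dtype=np.uint8)
    hairs = np.empty((n, size, size), dtype=np.uint8)
    for i in range(n):
        srng = np.random.default_rng(child_seeds[2 * i])
        spec = sample_lesion_spec(size, size, srng, low_contrast=bool(low[i]))
        bg = gen_background(size, size, int(child_seeds[2 * i]) % (2 ** 31))
        mask = gen_lesion_mask(size, size, spec, int(child_seeds[2 * i + 1]) % (2 ** 31))
        img, ht = render_scene(bg, mask, spec, hair,
                               seed=int(child_seeds[2 * i + 1]) % (2 ** 31))
        images[i], masks[i], hairs[i] = img, mask, ht
    return images, masks, hairs


def generate_dataset(n: int, out_dir, seed: int = 0, size: int = 256,
                     hair: Optional[HairSpec] = HairSpec(),
                     low_contrast_frac: float = 0.3,
                     splits=(0.7, 0.15, 0.15)):
    """Write n PNG image/mask pairs plus a manifest CSV; returns manifest path.

    Split labels are assigned contiguously over the (already random) sample
    order according to ``splits`` fractions (train, val, test).
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, masks, hairs = generate_arrays(n, size=size, seed=seed, hair=hair,
                                           low_contrast_frac=low_contrast_frac)
    n_train = int(round(splits[0] * n))
    n_val = int(round(splits[1] * n))
    rows = []
    for i in range(n):
        split = ("train" if i < n_train
                 else "val" if i < n_train + n_val else "test")
        img_path = out_dir / f"img_{i:04d}.png"
        mask_path = out_dir / f"mask_{i:04d}.png"
        Image.fromarray(images[i]).save(img_path)
        Image.fromarray((masks[i] * 255).astype(np.uint8)).save(mask_path)
        row = {"image": img_path.name, "mask": mask_path.name,
               "split": split, "seed": seed}
        if hair is not None:
            hair_path = out_dir / f"hair_{i:04d}.png"
            Image.fromarray((hairs[i] * 255).astype(np.uint8)).save(hair_path)
            row["hair"] = hair_path.name
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return manifest
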