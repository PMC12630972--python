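"""Dermoscopic image preprocessing: hair removal, resizing, augmentation.

Hair strands are thin dark curvilinear occluders on brighter skin.  They are
detected with a morphological black-hat transform (closing minus image, with
a 17x17 rectangular structuring element), binarized at a strict threshold
T=50, and healed by fast-marching inpainting that propagates intensities
inward from the mask boundary.  Images are then resized to the network's
input size and scaled to [0, 1] by dividing by 255.

Paired augmentation applies one geometric transform to image and mask alike:
rotation within +/-30 deg, 10% width/height shifts, shear 0.2, zoom up to
40%, and random horizontal/vertical flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.transform import AffineTransform, resize, warp

__all__ = [
    "HairDetectionParams", "AugmentationConfig", "ProcessedPair",
    "to_grayscale", "black_hat", "hair_mask", "inpaint_hair",
    "resize_normalize", "augment_pair", "preprocess_pipeline",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class HairDetectionParams:
    kernel_h: int = 17
    kernel_w: int = 17
    threshold: float = 50
    inpaint_radius: int = 3

    def __post_init__(self):
        for k in (self.kernel_h, self.kernel_w):
            if k < 3 or k % 2 == 0:
                raise ValueError(f"kernel dims must be odd and >= 3, got {k}")
        if not 0 <= self.threshold <= 255:
            raise ValueError(f"threshold must lie in [0, 255], got {self.threshold}")
        if self.inpaint_radius < 1:
            raise ValueError("inpaint_radius must be >= 1")


@dataclass(frozen=True)
class AugmentationConfig:
    rotation_range: float = 30.0       # degrees
    width_shift: float = 0.10          # fraction of width
    height_shift: float = 0.10         # fraction of height
    shear: float = 0.2                 # radians
    zoom: float = 0.40                 # fraction; scale drawn in [1-z, 1+z]
    horizontal_flip: bool = True
    vertical_flip: bool = True

    def __post_init__(self):
        for v in (self.rotation_range, self.width_shift, self.height_shift,
                  self.shear, self.zoom):
            if v < 0:
                raise ValueError("augmentation ranges must be nonnegative")
        if self.width_shift >= 1 or self.height_shift >= 1:
            raise ValueError("shift fractions must be < 1")


@dataclass
class ProcessedPair:
    """Network-ready sample: image in [0,1], optional binary {0,1} mask."""
    image: np.ndarray
    mask: Optional[np.ndarray] = None
    hair: Optional[np.ndarray] = field(default=None, repr=False)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance reduction of an 8-bit RGB image, rounded back to uint8."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.uint8)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {image.shape}")
    return np.rint(image @ _LUMA).clip(0, 255).astype(np.uint8)


def black_hat(gray: np.ndarray,
              params: HairDetectionParams = HairDetectionParams()) -> np.ndarray:
    """Black-hat transform: morphological closing minus the image.

    Responds to dark structures thinner than the structuring element; the
    response is nonnegative everywhere and zero on constant images.  Border
    windows are clipped to the image (replicate-edge semantics).
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError(f"black_hat expects a grayscale map, got shape {gray.shape}")
    if params.kernel_h > gray.shape[0] or params.kernel_w > gray.shape[1]:
        raise ValueError(
            f"structuring element {params.kernel_h}x{params.kernel_w} exceeds "
            f"image {gray.shape[0]}x{gray.shape[1]}")
    g = gray.astype(np.int32)
    closed = ndimage.grey_erosion(
        ndimage.grey_dilation(g, size=(params.kernel_h, params.kernel_w),
                              mode="nearest"),
        size=(params.kernel_h, params.kernel_w), mode="nearest")
    return closed - g


def hair_mask(response: np.ndarray, threshold: float = 50) -> np.ndarray:
    """Binarize a black-hat response: 255 where response > T (strict), else 0."""
    response = np.asarray(response)
    if not np.all(np.isfinite(response)):
        raise ValueError("response map contains non-finite values")
    return np.where(response > threshold, 255, 0).astype(np.uint8)


def inpaint_hair(image: np.ndarray, mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Fill masked pixels by fast-marching propagation from the mask boundary.

    Unknown pixels are visited in order of increasing distance from known
    territory (the fast-marching arrival time for uniform speed) and each is
    reconstructed as the inverse-distance-weighted mean of already-known
    pixels within ``radius``.  Pixels outside the mask are returned bit-exact.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if mask.shape != image.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} does not match image "
                         f"{image.shape[:2]}")
    unknown = mask > 0
    if not unknown.any():
        return image.copy()
    if unknown.all():
        raise ValueError("mask covers the whole image: nothing to propagate from")

    chans = image[..., None] if image.ndim == 2 else image
    out = chans.astype(np.float64).copy()
    known = ~unknown

    dist = ndimage.distance_transform_edt(unknown)
    h, w = unknown.shape
    ys, xs = np.nonzero(unknown)
    heap = sorted(zip(dist[ys, xs], ys.tolist(), xs.tolist()))

    r = int(radius)
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    inside = (dy != 0) | (dx != 0)
    dy, dx = dy[inside], dx[inside]
    wgt = 1.0 / np.hypot(dy, dx)

    for _, y, x in heap:
        ny, nx = y + dy, x + dx
        ok = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        ny, nx, ww = ny[ok], nx[ok], wgt[ok]
        kk = known[ny, nx]
        if not kk.any():
            # isolated deep pixel: widen to the nearest known pixel
            yy, xx = np.nonzero(known)
            j = np.argmin((yy - y) ** 2 + (xx - x) ** 2)
            out[y, x] = out[yy[j], xx[j]]
        else:
            ww = ww[kk]
            out[y, x] = (out[ny[kk], nx[kk]] * ww[:, None]).sum(axis=0) / ww.sum()
        known[y, x] = True

    result = np.rint(out).clip(0, 255).astype(image.dtype)
    if image.ndim == 2:
        result = result[..., 0]
    result[~unknown] = image[~unknown]
    return result


def resize_normalize(image: np.ndarray, out_size: int = 256) -> np.ndarray:
    """Resample to out_size x out_size (bilinear) and scale to [0, 1]."""
    image = np.asarray(image)
    if image.size == 0 or image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("cannot resize a zero-area image")
    if image.shape[:2] == (out_size, out_size):
        resampled = image.astype(np.float64)
    else:
        resampled = resize(image.astype(np.float64), (out_size, out_size),
                           order=1, mode="reflect", anti_aliasing=False,
                           preserve_range=True)
    return np.clip(resampled / 255.0, 0.0, 1.0).astype(np.float32)


def _resize_mask(mask: np.ndarray, out_size: int) -> np.ndarray:
    if mask.shape == (out_size, out_size):
        return (mask > 0).astype(np.uint8)
    res = resize(mask.astype(np.float64), (out_size, out_size), order=0,
                 mode="constant", cval=0, anti_aliasing=False,
                 preserve_range=True)
    return (res > 0.5 * max(1, mask.max())).astype(np.uint8)


def augment_pair(image: np.ndarray, mask: np.ndarray,
                 config: AugmentationConfig = AugmentationConfig(),
                 seed=0):
    """Apply one random geometric transform to an aligned image/mask pair.

    The transform parameters are drawn uniformly within the config ranges
    from a stream seeded by ``seed``; the same seed reproduces the outputs
    bit-exactly.  Images are interpolated bilinearly with reflect padding;
    masks use nearest-neighbour with zero fill and are re-binarized.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape[:2]} "
                         "are not aligned")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = image.shape[:2]

    angle = rng.uniform(-config.rotation_range, config.rotation_range)
    tx = rng.uniform(-config.width_shift, config.width_shift) * w
    ty = rng.uniform(-config.height_shift, config.height_shift) * h
    shear = rng.uniform(-config.shear, config.shear)
    zoom = rng.uniform(1.0 - config.zoom, 1.0 + config.zoom)
    flip_h = config.horizontal_flip and rng.random() < 0.5
    flip_v = config.vertical_flip and rng.random() < 0.5

    img_out = image
    mask_out = mask
    if angle or tx or ty or shear or zoom != 1.0:
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        tf = (AffineTransform(translation=-center)
              + AffineTransform(rotation=np.deg2rad(angle), shear=shear,
                                scale=(zoom, zoom))
              + AffineTransform(translation=center + np.array([tx, ty])))
        img_out = warp(image.astype(np.float64), tf.inverse, order=1,
                       mode="reflect", preserve_range=True)
        mask_out = warp(mask.astype(np.float64), tf.inverse, order=0,
                        mode="constant", cval=0, preserve_range=True)
        img_out = img_out.astype(image.dtype) if np.issubdtype(
            image.dtype, np.integer) else img_out.astype(image.dtype)
        mask_out = (mask_out > 0.5 * max(1, int(mask.max()) or 1)).astype(mask.dtype)
        if mask.max() > 1:
            mask_out = mask_out * mask.max()
    if flip_h:
        img_out = img_out[:, ::-1].copy()
        mask_out = mask_out[:, ::-1].copy()
    if flip_v:
        img_out = img_out[::-1].copy()
        mask_out = mask_out[::-1].copy()
    return img_out, mask_out


def preprocess_pipeline(image: np.ndarray, mask: Optional[np.ndarray] = None,
                        params: HairDetectionParams = HairDetectionParams(),
                        do_hair_removal: bool = True,
                        out_size: int = 256,
                        keep_hair_mask: bool = False) -> ProcessedPair:
    """Full preprocessing: grayscale -> black-hat -> threshold -> inpaint ->
    resize -> normalize.  The ground-truth mask, if given, is resized with
    nearest-neighbour and re-binarized to {0,1}; it is never inpainted."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {image.shape}")
    if image.shape[0] < 64 or image.shape[1] < 64:
        raise ValueError("input images must be at least 64 x 64")

    detected = None
    cleaned = image
    if do_hair_removal:
        gray = to_grayscale(image)
        response = black_hat(gray, params)
        detected = hair_mask(response, params.threshold)
        if detected.any():
            cleaned = inpaint_hair(image, detected, params.inpaint_radius)

    out_img = resize_normalize(cleaned, out_size)
    out_mask = _resize_mask(mask, out_size) if mask is not None else None
    return ProcessedPair(image=out_img, mask=out_mask,
                         hair=detected if keep_hair_mask else None)
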