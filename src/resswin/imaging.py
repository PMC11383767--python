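"""Pixel-level preprocessing and the six-transform augmentation set.

Resizing uses bicubic interpolation with the Keys kernel

    W(x) = (a+2)|x|^3 - (a+3)|x|^2 + 1          for |x| <= 1
    W(x) = a|x|^3 - 5a|x|^2 + 8a|x| - 4a        for 1 < |x| < 2
    W(x) = 0                                    otherwise

with sharpness coefficient ``a = -0.5``: every target pixel is a weighted
average of its 16 nearest source neighbours with separable weights
``W(a - u) W(b - v)``.  Sampling aligns pixel centres (source coordinate
``(dst + 0.5) * scale - 0.5``) and clamps source indices at the borders.

The augmentation set holds exactly six transforms: rotation by 90 and 180
degrees, horizontal mirroring, brightness scaling by 0.9 and by 1.5, and a
Gaussian blur (emulating wind-blown dust softening the optics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "BicubicKernelParams",
    "AugmentOp",
    "DEFAULT_AUGMENTS",
    "cubic_kernel_weight",
    "resize_bicubic",
    "rotate",
    "mirror",
    "scale_brightness",
    "gaussian_blur",
    "gaussian_taps",
    "apply_augment",
    "read_image",
    "write_image",
    "validate_image",
]


@dataclass(frozen=True)
class BicubicKernelParams:
    """Sharpness coefficient of the piecewise-cubic interpolation kernel."""

    a: float = -0.5


@dataclass(frozen=True)
class AugmentOp:
    """One augmentation transform.

    ``factor`` is the brightness multiplier for dim/brighten; ``sigma`` and
    ``kernel_size`` parameterise the Gaussian blur.
    """

    name: str
    factor: float | None = None
    sigma: float | None = None
    kernel_size: int | None = None


DEFAULT_AUGMENTS: tuple[AugmentOp, ...] = (
    AugmentOp("rot90"),
    AugmentOp("rot180"),
    AugmentOp("mirror"),
    AugmentOp("dim", factor=0.9),
    AugmentOp("brighten", factor=1.5),
    AugmentOp("gauss", sigma=1.0, kernel_size=5),
)


def validate_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have positive height and width")
    return arr


def read_image(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(img: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB").save(path)


# ----------------------------------------------------------------- resizing

def cubic_kernel_weight(x, params: BicubicKernelParams | float = BicubicKernelParams()):
    """Keys interpolation kernel weight at signed offset ``x`` (vectorised)."""
    a = params.a if isinstance(params, BicubicKernelParams) else float(params)
    ax = np.abs(np.asarray(x, dtype=np.float64))
    inner = (a + 2.0) * ax ** 3 - (a + 3.0) * ax ** 2 + 1.0
    outer = a * ax ** 3 - 5.0 * a * ax ** 2 + 8.0 * a * ax - 4.0 * a
    w = np.where(ax <= 1.0, inner, np.where(ax < 2.0, outer, 0.0))
    return w if w.ndim else float(w)


def _resample_matrix(n_src: int, n_dst: int, a: float) -> np.ndarray:
    """(n_dst, n_src) matrix of 4-tap Keys weights with clamped borders."""
    scale = n_src / n_dst
    src = (np.arange(n_dst) + 0.5) * scale - 0.5
    base = np.floor(src).astype(np.int64)
    frac = src - base
    mat = np.zeros((n_dst, n_src), dtype=np.float64)
    rows = np.arange(n_dst)
    for offset in (-1, 0, 1, 2):
        w = cubic_kernel_weight(offset - frac, BicubicKernelParams(a))
        idx = np.clip(base + offset, 0, n_src - 1)
        np.add.at(mat, (rows, idx), w)
    return mat


def resize_bicubic(img: np.ndarray, target_h: int, target_w: int,
                   params: BicubicKernelParams = BicubicKernelParams()) -> np.ndarray:
    """Separable bicubic resize of an HxWx3 8-bit image."""
    arr = validate_image(img)
    if target_h < 1 or target_w < 1:
        raise ValueError("target size must be positive")
    ah = _resample_matrix(arr.shape[0], target_h, params.a)
    aw = _resample_matrix(arr.shape[1], target_w, params.a)
    work = arr.astype(np.float64)
    out = np.einsum("ih,hwc,jw->ijc", ah, work, aw, optimize=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# -------------------------------------------------------------- augmentation

def rotate(img: np.ndarray, degrees: int) -> np.ndarray:
    """Lossless rotation by 90 (clockwise) or 180 degrees."""
    arr = validate_image(img)
    if degrees == 90:
        return np.ascontiguousarray(np.rot90(arr, k=-1))
    if degrees == 180:
        return np.ascontiguousarray(np.rot90(arr, k=2))
    raise ValueError("rotation angle must be 90 or 180 degrees")


def mirror(img: np.ndarray) -> np.ndarray:
    """Horizontal (left-right) flip."""
    return np.ascontiguousarray(validate_image(img)[:, ::-1])


def scale_brightness(img: np.ndarray, factor: float) -> np.ndarray:
    """Multiply every channel value by ``factor``, round, clamp to [0, 255]."""
    if factor <= 0:
        raise ValueError("brightness factor must be positive")
    arr = validate_image(img).astype(np.float64)
    return np.clip(np.rint(arr * factor), 0, 255).astype(np.uint8)


def gaussian_taps(sigma: float, kernel_size: int) -> np.ndarray:
    """Discrete Gaussian taps exp(-k^2 / 2 sigma^2), normalised to sum 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError("kernel_size must be odd and positive")
    k = np.arange(kernel_size) - kernel_size // 2
    taps = np.exp(-0.5 * (k / sigma) ** 2)
    return taps / taps.sum()


def gaussian_blur(img: np.ndarray, sigma: float = 1.0, kernel_size: int = 5) -> np.ndarray:
    """Separable Gaussian blur with reflect border handling."""
    arr = validate_image(img).astype(np.float64)
    taps = gaussian_taps(sigma, kernel_size)
    out = ndimage.convolve1d(arr, taps, axis=0, mode="reflect")
    out = ndimage.convolve1d(out, taps, axis=1, mode="reflect")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def additive_gaussian_noise(img: np.ndarray, sigma: float, rng: np.random.Generator
                            ) -> np.ndarray:
    """Additive pixel noise; not part of the default six-transform set."""
    arr = validate_image(img).astype(np.float64)
    return np.clip(np.rint(arr + rng.normal(0.0, sigma, arr.shape)), 0, 255).astype(np.uint8)


def apply_augment(img: np.ndarray, op: AugmentOp) -> np.ndarray:
    """Dispatch one :class:`AugmentOp` to its transform."""
    if op.name == "rot90":
        return rotate(img, 90)
    if op.name == "rot180":
        return rotate(img, 180)
    if op.name == "mirror":
        return mirror(img)
    if op.name in ("dim", "brighten"):
        if op.factor is None:
            raise ValueError(f"{op.name} requires a brightness factor")
        return scale_brightness(img, op.factor)
    if op.name == "gauss":
        return gaussian_blur(img, op.sigma or 1.0, op.kernel_size or 5)
    raise ValueError(f"unknown augmentation op {op.name!r}")
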