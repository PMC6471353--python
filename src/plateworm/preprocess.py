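"""Fixed preprocessing chain for backlit plate images.

Worms attenuate the backlight, so they appear as dark, slender shapes on a
bright field and carry strong edge contrast.  The chain exploits that:

    grayscale -> Gaussian blur -> adaptive (Gaussian-weighted) binarization
              -> Sobel derivative [-1, 0, 1] in x and y

The blur suppresses hairline scratches on the dish; the adaptive threshold
turns local contrast into a clean two-valued map regardless of illumination
gradients; the 1-D central-difference Sobel pair then yields the gradient
field that the HOG descriptor consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``blur_kernel_size`` must be odd; ``blur_sigma`` <= 0 selects the
    conventional automatic width ``0.3 * ((k - 1) / 2 - 1) + 0.8``.
    ``enabled=False`` bypasses blur+binarization and feeds the Sobel
    operator the raw grayscale image instead (the "no preprocessing"
    ablation).
    """

    blur_kernel_size: int = 5
    blur_sigma: float = 0.0
    block_size: int = 101
    c: float = 3.0
    maxval: int = 255
    enabled: bool = True

    def as_dict(self) -> dict:
        return {
            "blur_kernel_size": self.blur_kernel_size,
            "blur_sigma": self.blur_sigma,
            "block_size": self.block_size,
            "c": self.c,
            "maxval": self.maxval,
            "enabled": self.enabled,
        }


@dataclass
class GradientField:
    """Per-pixel signed gradient pair (g_x, g_y) plus derived magnitude."""

    g_x: np.ndarray
    g_y: np.ndarray

    def __post_init__(self) -> None:
        if self.g_x.shape != self.g_y.shape:
            raise ValueError("g_x and g_y must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.g_x.shape

    def magnitude(self) -> np.ndarray:
        gx = self.g_x.astype(np.float64)
        gy = self.g_y.astype(np.float64)
        return np.sqrt(gx * gx + gy * gy)


def _auto_sigma(kernel_size: int) -> float:
    # the usual automatic Gaussian width for an odd k-tap kernel
    return 0.3 * ((kernel_size - 1) * 0.5 - 1.0) + 0.8


def gaussian_kernel_1d(kernel_size: int, sigma: float = 0.0) -> np.ndarray:
    """Sampled, unit-sum 1-D Gaussian of odd length ``kernel_size``."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    if kernel_size == 1:
        return np.ones(1)
    if sigma <= 0:
        sigma = _auto_sigma(kernel_size)
    half = kernel_size // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    w = np.exp(-(x * x) / (2.0 * sigma * sigma))
    return w / w.sum()


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an 8-bit RGB image to luma; pass grayscale through untouched.

    Uses the ITU-R BT.601 weights (0.299, 0.587, 0.114), rounded to the
    nearest integer.
    """
    if image.ndim == 2:
        return image.astype(np.uint8, copy=False)
    if image.ndim == 3 and image.shape[2] == 3:
        rgb = image.astype(np.float64)
        luma = rgb[..., 0] * 0.299 + rgb[..., 1] * 0.587 + rgb[..., 2] * 0.114
        return np.clip(np.rint(luma), 0, 255).astype(np.uint8)
    raise ValueError(
        f"expected a 2-D grayscale or H x W x 3 RGB image, got shape {image.shape}"
    )


def gaussian_blur(img: np.ndarray, kernel_size: int = 5, sigma: float = 0.0) -> np.ndarray:
    """Discrete Gaussian convolution with reflective borders, rounded to uint8."""
    if kernel_size % 2 == 0:
        raise ValueError(f"blur kernel size must be odd, got {kernel_size}")
    if kernel_size == 1:
        return img.astype(np.uint8, copy=True)
    w = gaussian_kernel_1d(kernel_size, sigma)
    out = img.astype(np.float64)
    out = ndimage.correlate1d(out, w, axis=0, mode="reflect")
    out = ndimage.correlate1d(out, w, axis=1, mode="reflect")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def adaptive_binarize(
    img: np.ndarray,
    block_size: int = 101,
    c: float = 3.0,
    maxval: int = 255,
) -> np.ndarray:
    """Binarize against a local Gaussian-weighted mean.

    The threshold at each pixel is the Gaussian-weighted mean of its
    ``block_size`` x ``block_size`` neighborhood (reflective borders) minus
    the constant ``c``; pixels strictly above their threshold map to
    ``maxval``, all others to 0.
    """
    if block_size < 3 or block_size % 2 == 0:
        raise ValueError(f"block_size must be odd and >= 3, got {block_size}")
    w = gaussian_kernel_1d(block_size)
    mean = img.astype(np.float64)
    mean = ndimage.correlate1d(mean, w, axis=0, mode="reflect")
    mean = ndimage.correlate1d(mean, w, axis=1, mode="reflect")
    out = np.where(img.astype(np.float64) > mean - c, maxval, 0)
    return out.astype(np.uint8)


def sobel_gradients(img: np.ndarray) -> GradientField:
    """Signed central-difference derivatives [-1, 0, 1] along x and y.

    ``g_x`` responds to horizontal intensity change (vertical edges), ``g_y``
    to vertical change.  Borders are reflected.  The input is widened to a
    signed type so 8-bit differences cannot wrap.
    """
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    kernel = np.array([-1, 0, 1], dtype=np.int64)
    src = img.astype(np.int64)
    g_x = ndimage.correlate1d(src, kernel, axis=1, mode="reflect")
    g_y = ndimage.correlate1d(src, kernel, axis=0, mode="reflect")
    return GradientField(g_x=g_x, g_y=g_y)


def preprocess(image: np.ndarray, config: PreprocessConfig | None = None) -> GradientField:
    """Run the full chain on an RGB or grayscale image.

    With ``config.enabled`` false the adaptive binarization is skipped and
    gradients are taken from the blurred grayscale image directly.
    """
    cfg = config or PreprocessConfig()
    gray = to_grayscale(image)
    blurred = gaussian_blur(gray, cfg.blur_kernel_size, cfg.blur_sigma)
    if cfg.enabled:
        source = adaptive_binarize(blurred, cfg.block_size, cfg.c, cfg.maxval)
    else:
        source = blurred
    return sobel_gradients(source)
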