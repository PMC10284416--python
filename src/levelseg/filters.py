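"""Gaussian and bilateral smoothing — the pre-processing stage of the model.

The bilateral filter weights each neighbour by a spatial Gaussian of the
pixel offset times a range Gaussian of the intensity difference to the raw
centre pixel, normalized per pixel:

    out(p) = (1/Wp) * sum_q  Gs(|p-q|) * Gr(|I(p)-I(q)|) * I(q),
    Wp     =          sum_q  Gs(|p-q|) * Gr(|I(p)-I(q)|)

Both filters use replicate (nearest-edge) padding so constant images are
fixed points and frame borders do not darken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image import GrayImage

__all__ = [
    "GaussianSpec",
    "BilateralSpec",
    "gaussian_kernel",
    "gaussian_smooth",
    "bilateral_smooth",
    "bilateral_smooth_bruteforce",
]


def _default_radius(sigma: float) -> int:
    # 3-sigma truncation keeps > 99.6% of the kernel mass
    return max(1, math.ceil(3.0 * sigma))


@dataclass(frozen=True)
class GaussianSpec:
    """Truncated Gaussian kernel: standard deviation and half-width."""

    sigma: float
    radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")
        if self.radius is None:
            object.__setattr__(self, "radius", _default_radius(self.sigma))
        elif self.radius < 1:
            raise ValidationError(f"radius must be >= 1, got {self.radius}")


@dataclass(frozen=True)
class BilateralSpec:
    """Bilateral kernel: spatial width (px), range width (intensity), radius."""

    sigma_s: float
    sigma_r: float
    radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_s <= 0:
            raise ValidationError(f"sigma_s must be > 0, got {self.sigma_s}")
        if self.sigma_r <= 0:
            raise ValidationError(f"sigma_r must be > 0, got {self.sigma_r}")
        if self.radius is None:
            object.__setattr__(self, "radius", _default_radius(self.sigma_s))
        elif self.radius < _default_radius(self.sigma_s):
            raise ValidationError(
                f"radius must be >= ceil(3*sigma_s) = "
                f"{_default_radius(self.sigma_s)}, got {self.radius}"
            )


def gaussian_kernel(spec: GaussianSpec) -> np.ndarray:
    """(2r+1)x(2r+1) Gaussian kernel normalized to sum exactly 1."""
    offsets = np.arange(-spec.radius, spec.radius + 1, dtype=np.float64)
    dy2 = offsets[:, None] ** 2
    dx2 = offsets[None, :] ** 2
    kernel = np.exp(-(dy2 + dx2) / (2.0 * spec.sigma**2))
    return kernel / kernel.sum()


def gaussian_smooth(image: GrayImage, spec: GaussianSpec) -> GrayImage:
    """Convolve with the truncated Gaussian kernel, replicate padding."""
    out = ndimage.convolve(image.pixels, gaussian_kernel(spec), mode="nearest")
    return GrayImage(np.clip(out, 0.0, image.value_range), image.value_range)


def _spatial_weights(sigma_s: float, radius: int) -> np.ndarray:
    offsets = np.arange(-radius, radius + 1, dtype=np.float64)
    return np.exp(
        -(offsets[:, None] ** 2 + offsets[None, :] ** 2) / (2.0 * sigma_s**2)
    )


def bilateral_smooth(image: GrayImage, spec: BilateralSpec) -> GrayImage:
    """Edge-preserving bilateral filter (window shift-and-accumulate)."""
    src = image.pixels
    r = spec.radius
    h, w = src.shape
    padded = np.pad(src, r, mode="edge")
    ws = _spatial_weights(spec.sigma_s, r)
    inv_two_sr2 = 1.0 / (2.0 * spec.sigma_r**2)
    num = np.zeros_like(src)
    den = np.zeros_like(src)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            shifted = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            weight = ws[dy + r, dx + r] * np.exp(
                -((shifted - src) ** 2) * inv_two_sr2
            )
            num += weight * shifted
            den += weight
    out = num / den  # den >= centre weight == 1 always
    return GrayImage(np.clip(out, 0.0, image.value_range), image.value_range)


def bilateral_smooth_bruteforce(
    image: GrayImage, spec: BilateralSpec
) -> GrayImage:
    """Reference bilateral filter: literal per-pixel double loop.

    Kept deliberately naive as an independent oracle for the vectorized
    implementation; do not use on large images.
    """
    src = image.pixels
    r = spec.radius
    h, w = src.shape
    padded = np.pad(src, r, mode="edge")
    two_ss2 = 2.0 * spec.sigma_s**2
    two_sr2 = 2.0 * spec.sigma_r**2
    out = np.empty_like(src)
    for i in range(h):
        for j in range(w):
            centre = src[i, j]
            num = 0.0
            den = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    q = padded[i + r + dy, j + r + dx]
                    weight = math.exp(
                        -(dy * dy + dx * dx) / two_ss2
                        - (q - centre) ** 2 / two_sr2
                    )
                    num += weight * q
                    den += weight
            out[i, j] = num / den
    return GrayImage(np.clip(out, 0.0, image.value_range), image.value_range)
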