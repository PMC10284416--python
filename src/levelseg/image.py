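"""Grayscale image container, raster I/O and synthetic test scenes.

Images are stored as 2-D float arrays on the 0..255 scale (8-bit convention)
regardless of the on-disk dtype; ``value_range`` records the declared peak.
Indexing is (row, col) and 0-based everywhere except :class:`Region`, which
mirrors the 1-based inclusive ``[a:b],[c:d]`` crop notation used in printed
evaluation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

from .errors import ValidationError

__all__ = [
    "GrayImage",
    "Region",
    "SceneTruth",
    "read_gray",
    "write_gray",
    "make_disk_image",
    "add_gaussian_noise",
    "crop_region",
]

_MIN_SIDE = 3  # evolution stencils need at least one interior pixel


@dataclass
class GrayImage:
    """A 2-D grayscale intensity field.

    Parameters
    ----------
    pixels
        2-D float array of intensities, ``0 <= pixels <= value_range``.
    value_range
        Declared peak value (255 for 8-bit provenance, 1.0 for unit floats).
    """

    pixels: np.ndarray
    value_range: float = 255.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValidationError(f"pixels must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < _MIN_SIDE or arr.shape[1] < _MIN_SIDE:
            raise ValidationError(
                f"image must be at least {_MIN_SIDE}x{_MIN_SIDE}, got {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("pixels contain non-finite values")
        if arr.min() < 0 or arr.max() > self.value_range:
            raise ValidationError(
                f"pixel values [{arr.min()}, {arr.max()}] outside "
                f"[0, {self.value_range}]"
            )
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Region:
    """1-based inclusive crop window, the ``{[a:b],[c:d]}`` table notation.

    The first bracket is rows, the second columns.
    """

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.row_start <= self.row_end):
            raise ValidationError(
                f"bad row range [{self.row_start}:{self.row_end}]"
            )
        if not (1 <= self.col_start <= self.col_end):
            raise ValidationError(
                f"bad col range [{self.col_start}:{self.col_end}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (
            self.row_end - self.row_start + 1,
            self.col_end - self.col_start + 1,
        )

    def slices(self) -> tuple[slice, slice]:
        """0-based half-open slices equivalent to this region."""
        return (
            slice(self.row_start - 1, self.row_end),
            slice(self.col_start - 1, self.col_end),
        )

    @classmethod
    def parse(cls, text: str) -> "Region":
        """Parse ``"r0:r1,c0:c1"`` into a Region."""
        try:
            rows, cols = text.split(",")
            r0, r1 = (int(v) for v in rows.split(":"))
            c0, c1 = (int(v) for v in cols.split(":"))
        except Exception as exc:  # noqa: BLE001 - normalized below
            raise ValidationError(f"cannot parse region {text!r}") from exc
        return cls(r0, r1, c0, c1)


@dataclass
class SceneTruth:
    """Ground truth for a synthetic scene: mask, boundary samples, noise."""

    mask: np.ndarray
    boundary: np.ndarray  # (n, 2) sub-pixel (row, col) points
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        n = int(mask.sum())
        if n == 0 or n == mask.size:
            raise ValidationError("truth mask must be non-empty and not full-frame")
        boundary = np.asarray(self.boundary, dtype=np.float64)
        if boundary.ndim != 2 or boundary.shape[1] != 2:
            raise ValidationError("boundary must be an (n, 2) point array")
        h, w = mask.shape
        if (
            boundary[:, 0].min() < 0
            or boundary[:, 0].max() > h - 1
            or boundary[:, 1].min() < 0
            or boundary[:, 1].max() > w - 1
        ):
            raise ValidationError("boundary points fall outside the image")
        self.mask = mask
        self.boundary = boundary


def read_gray(path) -> GrayImage:
    """Read PNG/TIFF/PGM into a canonical 0..255 float grayscale image.

    Multi-channel inputs are collapsed by the unweighted channel mean.
    Float inputs in [0, 1] are rescaled to [0, 255].
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"image {path!r} is empty")
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    elif arr.ndim != 2:
        raise ValidationError(f"unsupported image dimensionality {arr.ndim}")
    if arr.max() <= 1.0 and arr.min() >= 0.0:
        arr = arr * 255.0
    return GrayImage(np.clip(arr, 0.0, 255.0), value_range=255.0)


def write_gray(path, image: GrayImage) -> None:
    """Write an image as 8-bit grayscale (rounding to the nearest level)."""
    scale = 255.0 / image.value_range
    data = np.clip(np.rint(image.pixels * scale), 0, 255).astype(np.uint8)
    iio.imwrite(path, data)


def make_disk_image(
    height: int,
    width: int,
    center: tuple[float, float],
    radius: float,
    fg: float = 200.0,
    bg: float = 50.0,
) -> tuple[GrayImage, SceneTruth]:
    """Synthesize a single-disk scene with exact ground truth.

    The foreground is the lattice set ``(r-cr)^2 + (c-cc)^2 <= radius^2``;
    the truth boundary is a dense sampling of the ideal circle.
    """
    if radius < 3:
        raise ValidationError(f"radius must be >= 3 px, got {radius}")
    cr, cc = center
    if (
        cr - radius < 2
        or cc - radius < 2
        or cr + radius > height - 3
        or cc + radius > width - 3
    ):
        raise ValidationError(
            "disk must lie fully inside the frame with a >= 2 px margin"
        )
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    mask = (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2
    pixels = np.where(mask, float(fg), float(bg))
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    boundary = np.column_stack(
        [cr + radius * np.sin(theta), cc + radius * np.cos(theta)]
    )
    image = GrayImage(pixels, value_range=255.0)
    return image, SceneTruth(mask=mask, boundary=boundary)


def add_gaussian_noise(image: GrayImage, sigma: float, seed: int) -> GrayImage:
    """Add i.i.d. Gaussian noise, clipping back into the valid range."""
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return GrayImage(image.pixels.copy(), image.value_range)
    rng = np.random.default_rng(seed)
    noisy = image.pixels + rng.normal(0.0, sigma, size=image.shape)
    return GrayImage(
        np.clip(noisy, 0.0, image.value_range), value_range=image.value_range
    )


def crop_region(image: GrayImage, region: Region) -> GrayImage:
    """Crop by a 1-based inclusive region (rows first, then columns)."""
    if region.row_end > image.height:
        raise ValidationError(
            f"row_end {region.row_end} exceeds image height {image.height}"
        )
    if region.col_end > image.width:
        raise ValidationError(
            f"col_end {region.col_end} exceeds image width {image.width}"
        )
    rs, cs = region.slices()
    return GrayImage(image.pixels[rs, cs].copy(), value_range=image.value_range)
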