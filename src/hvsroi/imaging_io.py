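"""Raster and mask I/O, color decomposition and Gaussian pyramids.

All raster data is carried as float64 numpy arrays with values in [0, 1].
An :class:`RGBImage` is an ``(H, W, 3)`` array wrapper; single-channel
"planes" are plain ``(H, W)`` float arrays.  The Gaussian pyramid uses a
separable 5-tap binomial kernel and a fixed smooth-then-subsample schedule
so every level shape is ``ceil(previous / 2)`` — deterministic by
construction, which the downstream oracle tests rely on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy.ndimage import convolve1d

logger = logging.getLogger(__name__)

#: Separable 5-tap binomial approximation of a Gaussian; sums to 1 exactly.
BINOMIAL_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0

#: Default number of pyramid levels (scales 0-8).
DEFAULT_PYRAMID_LEVELS = 9


class ImageDecodeError(RuntimeError):
    """Raised when a raster file cannot be read or decoded."""


@dataclass(frozen=True)
class RGBImage:
    """A 3-channel raster with float64 values in [0, 1].

    Attributes
    ----------
    data : ndarray, shape (H, W, 3)
        Channel-last pixel data.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"RGBImage requires an (H, W, 3) array, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("RGBImage values must be finite")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("RGBImage values must lie in [0, 1]")
        object.__setattr__(self, "data", arr)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def r(self) -> np.ndarray:
        return self.data[:, :, 0]

    @property
    def g(self) -> np.ndarray:
        return self.data[:, :, 1]

    @property
    def b(self) -> np.ndarray:
        return self.data[:, :, 2]


@dataclass(frozen=True)
class Pyramid:
    """Ordered list of planes; level 0 is full resolution and level ``L``
    has shape ``ceil(dim / 2**L)`` of level 0."""

    levels: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise ValueError("Pyramid needs at least one level")
        object.__setattr__(self, "levels", tuple(self.levels))

    def __len__(self) -> int:
        return len(self.levels)

    def __getitem__(self, level: int) -> np.ndarray:
        return self.levels[level]


@dataclass(frozen=True)
class BinaryMask:
    """A {0, 1} raster stored as uint8."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"BinaryMask requires a 2-D array, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("BinaryMask values must be 0 or 1")
        object.__setattr__(self, "values", arr.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)


def read_image(path: str | Path) -> RGBImage:
    """Read a JPEG/PNG/TIFF raster into an :class:`RGBImage` in [0, 1].

    Grayscale sources are replicated to three channels; 8- and 16-bit
    integer data are scaled by their dtype maximum so 255 (or 65535)
    maps to exactly 1.0.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = _pil_to_float(im)
    except (OSError, UnidentifiedImageError, ValueError) as exc:
        raise ImageDecodeError(f"cannot decode raster file {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return RGBImage(arr)


def _pil_to_float(im: Image.Image) -> np.ndarray:
    if im.mode in ("RGBA", "LA", "P"):
        im = im.convert("RGB")
    arr = np.asarray(im)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / info.max
    arr = arr.astype(np.float64)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("float raster values outside [0, 1]")
    return arr


def write_image(img: RGBImage, path: str | Path) -> None:
    """Write an :class:`RGBImage` as an 8-bit raster (format from suffix)."""
    arr = np.round(img.data * 255.0).astype(np.uint8)
    Image.fromarray(arr).save(Path(path))


def to_intensity(img: RGBImage) -> np.ndarray:
    """Per-pixel arithmetic mean of the r, g, b channels."""
    return (img.r + img.g + img.b) / 3.0


def opponent_channels(
    img: RGBImage,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Broadly-tuned color channels (R, G, B, Y), clamped below at 0.

    R = r - (g+b)/2, G = g - (r+b)/2, B = b - (r+g)/2,
    Y = (r+g)/2 - |r-g|/2 - b.
    """
    r, g, b = img.r, img.g, img.b
    R = np.maximum(r - (g + b) / 2.0, 0.0)
    G = np.maximum(g - (r + b) / 2.0, 0.0)
    B = np.maximum(b - (r + g) / 2.0, 0.0)
    Y = np.maximum((r + g) / 2.0 - np.abs(r - g) / 2.0 - b, 0.0)
    return R, G, B, Y


def _smooth(plane: np.ndarray) -> np.ndarray:
    out = convolve1d(plane, BINOMIAL_KERNEL, axis=0, mode="reflect")
    return convolve1d(out, BINOMIAL_KERNEL, axis=1, mode="reflect")


def gaussian_pyramid(plane: np.ndarray, n_levels: int = DEFAULT_PYRAMID_LEVELS) -> Pyramid:
    """Smooth-then-subsample pyramid; level ``L`` has dims ``ceil(dim/2**L)``.

    Level 0 is the input itself.  If a requested level would have a
    dimension below 1 pixel the level count is truncated with a warning.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError("gaussian_pyramid expects a 2-D plane")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    levels = [plane]
    for _ in range(1, n_levels):
        prev = levels[-1]
        if prev.shape[0] < 2 or prev.shape[1] < 2:
            warnings.warn(
                f"pyramid truncated at {len(levels)} levels "
                f"(next level would fall below 1 pixel from shape {prev.shape})",
                stacklevel=2,
            )
            break
        # Taking every other sample starting at 0 gives ceil(n/2) dims.
        levels.append(_smooth(prev)[::2, ::2])
    return Pyramid(tuple(levels))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a raster as a binary mask: any nonzero value (in any channel)
    maps to 1."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except (OSError, UnidentifiedImageError) as exc:
        raise ImageDecodeError(f"cannot decode mask file {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = np.any(arr != 0, axis=-1)
    return BinaryMask((arr != 0).astype(np.uint8))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a single-channel 0/255 PNG (lossless)."""
    Image.fromarray(mask.values * np.uint8(255), mode="L").save(Path(path))
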