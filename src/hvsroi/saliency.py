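"""Bottom-up local-relevance (saliency) map.

Center–surround feature maps for intensity, color opponency and
orientation are computed over a 9-level Gaussian pyramid, promoted with a
local-maxima normalization operator, summed at a common working scale
(pyramid level 4) and combined into a single saliency map in [0, 1].

Fixed conventions (required by the oracle tests):

* upsampling/downsampling is align-corners bilinear everywhere
  (:func:`resize_bilinear`);
* center scales c ∈ {2, 3, 4}, surround scales s = c + δ, δ ∈ {3, 4},
  truncated to the available pyramid depth;
* Gabor angles θ ∈ {0°, 45°, 90°, 135°}, where θ names the *edge*
  orientation (a vertical edge responds maximally at θ = 90°);
* the Gabor kernel's real part is shifted to zero mean so constant
  input yields exactly zero response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.ndimage import (
    binary_dilation,
    convolve,
    label,
    map_coordinates,
    maximum_filter,
)
from skimage.filters import gabor_kernel

from hvsroi.imaging_io import (
    DEFAULT_PYRAMID_LEVELS,
    Pyramid,
    RGBImage,
    gaussian_pyramid,
    opponent_channels,
    to_intensity,
)

logger = logging.getLogger(__name__)

GABOR_ANGLES_DEG = (0.0, 45.0, 90.0, 135.0)
CENTER_SCALES = (2, 3, 4)
SURROUND_DELTAS = (3, 4)
WORKING_SCALE = 4
GABOR_FREQUENCY = 0.25


@dataclass(frozen=True)
class SaliencyMap:
    """Saliency plane in [0, 1] at source-image resolution, plus the
    normalization record (global max and mean-of-other-local-maxima of the
    combined working-scale map before rescaling)."""

    values: np.ndarray
    global_max: float
    mean_other_maxima: float


def resize_bilinear(plane: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Align-corners bilinear resampling to ``shape``.

    Output pixel (i, j) samples the input at
    ``(i*(H-1)/(h-1), j*(W-1)/(w-1))`` (0 when the target dim is 1).
    """
    plane = np.asarray(plane, dtype=np.float64)
    h, w = shape
    H, W = plane.shape
    rows = np.zeros(h) if h == 1 else np.arange(h) * ((H - 1) / (h - 1))
    cols = np.zeros(w) if w == 1 else np.arange(w) * ((W - 1) / (w - 1))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(plane, [rr, cc], order=1, mode="nearest")


def center_surround(pyr: Pyramid, c: int, s: int) -> np.ndarray:
    """Across-scale difference |pyr[c] − upsample(pyr[s])| at level-c
    resolution; non-negative by construction."""
    if s <= c:
        raise ValueError(f"surround level s={s} must exceed center level c={c}")
    if c >= len(pyr) or s >= len(pyr):
        raise ValueError(
            f"center_surround needs levels c={c}, s={s} but pyramid has {len(pyr)}"
        )
    center = pyr[c]
    surround = resize_bilinear(pyr[s], center.shape)
    return np.abs(center - surround)


@lru_cache(maxsize=8)
def _gabor_kernels(theta_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """(even, odd) Gabor kernel pair for an *edge* angle, real part
    shifted to zero mean."""
    if theta_deg not in GABOR_ANGLES_DEG:
        raise ValueError(
            f"unsupported Gabor angle {theta_deg}; choose from {GABOR_ANGLES_DEG}"
        )
    # Edge-orientation convention: θ names the direction along the edge,
    # so the carrier wave runs perpendicular to it.
    carrier = np.deg2rad(theta_deg - 90.0)
    k = gabor_kernel(frequency=GABOR_FREQUENCY, theta=carrier)
    even = np.real(k)
    even = even - even.mean()
    odd = np.imag(k)
    return even, odd


def gabor_filter(plane: np.ndarray, theta_deg: float) -> np.ndarray:
    """Magnitude of the quadrature Gabor response at an edge angle."""
    even, odd = _gabor_kernels(theta_deg)
    re = convolve(np.asarray(plane, dtype=np.float64), even, mode="reflect")
    im = convolve(np.asarray(plane, dtype=np.float64), odd, mode="reflect")
    return np.hypot(re, im)


def gabor_orientation_pyramid(
    intensity: np.ndarray,
    theta_deg: float,
    n_levels: int = DEFAULT_PYRAMID_LEVELS,
) -> Pyramid:
    """Per-level oriented band-pass energy of the intensity pyramid."""
    pyr = gaussian_pyramid(intensity, n_levels)
    return Pyramid(tuple(gabor_filter(lvl, theta_deg) for lvl in pyr.levels))


def _local_maxima_values(plane: np.ndarray) -> np.ndarray:
    """Values of strict 8-neighborhood local maxima; a constant plateau
    counts once (connected-component reduction).  Only in-bounds
    neighbors are compared."""
    eight = np.ones((3, 3), dtype=bool)
    cand = plane >= maximum_filter(plane, size=3, mode="reflect")
    labels, n = label(cand, structure=eight)
    values = []
    for comp in range(1, n + 1):
        sel = labels == comp
        v = plane[sel][0]
        ring = binary_dilation(sel, structure=eight) & ~sel
        # Strictness: the plateau must exceed every pixel touching it.
        if not ring.any() or plane[ring].max() < v:
            values.append(v)
    return np.asarray(values, dtype=np.float64)


def normalize_map(plane: np.ndarray) -> np.ndarray:
    """Map-promotion operator: rescale to [0, 1] then multiply by
    (M − m̄)² where M = 1 (the global max after rescaling) and m̄ is the
    mean of all *other* local maxima (0 when there are none)."""
    plane = np.asarray(plane, dtype=np.float64)
    lo, hi = plane.min(), plane.max()
    if hi == lo:
        return np.zeros_like(plane)
    scaled = (plane - lo) / (hi - lo)
    maxima = _local_maxima_values(scaled)
    others = np.delete(maxima, int(np.argmax(maxima))) if maxima.size else maxima
    m_bar = float(others.mean()) if others.size else 0.0
    return scaled * (1.0 - m_bar) ** 2


def _scale_pairs(n_levels: int) -> list[tuple[int, int]]:
    pairs = [
        (c, c + d)
        for c in CENTER_SCALES
        for d in SURROUND_DELTAS
        if c + d < n_levels and c < n_levels
    ]
    if len(pairs) < len(CENTER_SCALES) * len(SURROUND_DELTAS):
        logger.info(
            "pyramid depth %d supports only %d center-surround pairs", n_levels, len(pairs)
        )
    if not pairs:
        raise ValueError(
            f"image too small for any center-surround pair (pyramid depth {n_levels})"
        )
    return pairs


def _working_shape(pyr: Pyramid) -> tuple[int, int]:
    lvl = min(WORKING_SCALE, len(pyr) - 1)
    return pyr[lvl].shape


def conspicuity_maps(
    img: RGBImage, n_levels: int = DEFAULT_PYRAMID_LEVELS
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intensity, color and orientation conspicuity maps at the working
    scale, each passed through :func:`normalize_map`.

    Composition (mirrored verbatim by the compositional oracle test):

    * I̅ = N( Σ_{c,s} resize(N(|I_c − up(I_s)|)) )
    * C̅ = N( Σ_{c,s} resize(N(RG(c,s))) + resize(N(BY(c,s))) ) with
      RG(c,s) = |(R−G)_c + up((R−G)_s)|, BY likewise from (B−Y)
    * O̅ = N( Σ_θ N( Σ_{c,s} resize(N(|O_c(θ) − up(O_s(θ))|)) ) )
    """
    intensity = to_intensity(img)
    ipyr = gaussian_pyramid(intensity, n_levels)
    pairs = _scale_pairs(len(ipyr))
    work = _working_shape(ipyr)

    def promote_resize(m: np.ndarray) -> np.ndarray:
        return resize_bilinear(normalize_map(m), work)

    i_bar = np.zeros(work)
    for c, s in pairs:
        i_bar += promote_resize(center_surround(ipyr, c, s))
    i_bar = normalize_map(i_bar)

    R, G, B, Y = opponent_channels(img)
    rg_pyr = gaussian_pyramid(R - G, n_levels)
    by_pyr = gaussian_pyramid(B - Y, n_levels)
    c_bar = np.zeros(work)
    for c, s in pairs:
        for pyr in (rg_pyr, by_pyr):
            # Double opponency: center (A−B) against surround (B−A).
            m = np.abs(pyr[c] + resize_bilinear(pyr[s], pyr[c].shape))
            c_bar += promote_resize(m)
    c_bar = normalize_map(c_bar)

    o_bar = np.zeros(work)
    for theta in GABOR_ANGLES_DEG:
        opyr = gabor_orientation_pyramid(intensity, theta, n_levels)
        per_angle = np.zeros(work)
        for c, s in pairs:
            per_angle += promote_resize(center_surround(opyr, c, s))
        o_bar += normalize_map(per_angle)
    o_bar = normalize_map(o_bar)

    return i_bar, c_bar, o_bar


def combine_conspicuity(
    i_bar: np.ndarray,
    c_bar: np.ndarray,
    o_bar: np.ndarray,
    out_shape: tuple[int, int],
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> SaliencyMap:
    """Weighted mean of the promoted conspicuity maps, upsampled to
    ``out_shape`` and rescaled to [0, 1] (all-zero stays all-zero)."""
    wi, wc, wo = weights
    total = wi + wc + wo
    combined = (
        wi * normalize_map(i_bar) + wc * normalize_map(c_bar) + wo * normalize_map(o_bar)
    ) / total
    maxima = _local_maxima_values(combined)
    if maxima.size:
        others = np.delete(maxima, int(np.argmax(maxima)))
        m_bar = float(others.mean()) if others.size else 0.0
    else:
        m_bar = 0.0
    full = resize_bilinear(combined, out_shape)
    hi = full.max()
    values = full / hi if hi > 0 else np.zeros_like(full)
    values = np.clip(values, 0.0, 1.0)
    return SaliencyMap(values=values, global_max=float(hi), mean_other_maxima=m_bar)


def saliency_map(img: RGBImage, n_levels: int = DEFAULT_PYRAMID_LEVELS) -> SaliencyMap:
    """Combined saliency: unweighted mean of the promoted conspicuity
    maps, upsampled to image resolution and rescaled to [0, 1]."""
    i_bar, c_bar, o_bar = conspicuity_maps(img, n_levels)
    return combine_conspicuity(i_bar, c_bar, o_bar, (img.height, img.width))
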