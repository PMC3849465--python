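"""Texton database construction and saliency-ordered kNN target search.

A texton is a 32×32 RGB patch.  Its feature vector (I, O, C, H) mirrors
the per-region summary features but is computed over the patch footprint:
mean intensity, mean quadrature Gabor energy over the four angles, mean
color-opponency energy, and the Shannon entropy (bits) of the patch's
quantized intensity histogram.  Classification is a classical kNN with
Euclidean distance in z-normalized feature space; regions are visited in
decreasing attention order until the first carcinoma-like region is
found.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from hvsroi.imaging_io import BinaryMask, RGBImage
from hvsroi.regions import (
    DEFAULT_ENTROPY_BINS,
    RegionMap,
    RegionSummary,
    order_by_attention,
    quantize_intensity,
)
from hvsroi.saliency import GABOR_ANGLES_DEG, gabor_filter

logger = logging.getLogger(__name__)

TEXTON_SIZE = 32
ROI_LABEL = "roi"
BACKGROUND_LABEL = "background"

DEFAULT_K = 5
DEFAULT_TEXTONS_PER_REGION = 20
DEFAULT_VOTE_THRESHOLD = 0.5


class FeatureVector(NamedTuple):
    """Low-level patch features in the fixed order (I, O, C, H)."""

    I: float
    O: float
    C: float
    H: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=np.float64)


@dataclass(frozen=True)
class Texton:
    """A 32×32×3 exemplar patch with provenance and (optionally) a class
    label from training."""

    patch: np.ndarray
    source: tuple[str, int, int]
    label: str | None = None

    def __post_init__(self) -> None:
        patch = np.asarray(self.patch, dtype=np.float64)
        if patch.shape != (TEXTON_SIZE, TEXTON_SIZE, 3):
            raise ValueError(
                f"texton patch must be {TEXTON_SIZE}x{TEXTON_SIZE}x3, got {patch.shape}"
            )
        object.__setattr__(self, "patch", patch)


@dataclass
class TextonDatabase:
    """Labeled exemplar vectors with fitted per-dimension z-normalization.

    Dimensions with zero standard deviation are excluded from the metric
    (``active_dims``).
    """

    vectors: np.ndarray
    labels: list[str]
    mean: np.ndarray
    sd: np.ndarray
    active_dims: np.ndarray
    feature_mode: str = "derived"

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def transform(self, v: np.ndarray) -> np.ndarray:
        """z-score a probe vector on the active dimensions."""
        v = np.asarray(v, dtype=np.float64)
        act = self.active_dims
        return (v[act] - self.mean[act]) / self.sd[act]

    def save(self, path: str | Path) -> None:
        payload = {
            "vectors": self.vectors.tolist(),
            "labels": self.labels,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "active_dims": self.active_dims.astype(int).tolist(),
            "feature_mode": self.feature_mode,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TextonDatabase":
        payload = json.loads(Path(path).read_text())
        return cls(
            vectors=np.asarray(payload["vectors"], dtype=np.float64),
            labels=list(payload["labels"]),
            mean=np.asarray(payload["mean"], dtype=np.float64),
            sd=np.asarray(payload["sd"], dtype=np.float64),
            active_dims=np.asarray(payload["active_dims"], dtype=bool),
            feature_mode=payload.get("feature_mode", "derived"),
        )


@dataclass(frozen=True)
class SearchResult:
    """Outcome of the attention-ordered search: the first target region
    (if any), the examined prefix, and per-region roi vote fractions."""

    target_region_id: int | None
    regions_examined: tuple[int, ...]
    vote_fractions: dict[int, float]


def _valid_top_lefts(allowed: np.ndarray, size: int = TEXTON_SIZE) -> np.ndarray:
    """(row, col) top-left corners whose size×size window lies entirely
    in the ``allowed`` boolean plane."""
    h, w = allowed.shape
    if h < size or w < size:
        return np.empty((0, 2), dtype=np.int64)
    csum = np.cumsum(np.cumsum(allowed.astype(np.int64), axis=0), axis=1)
    padded = np.zeros((h + 1, w + 1), dtype=np.int64)
    padded[1:, 1:] = csum
    win = (
        padded[size:, size:]
        - padded[:-size, size:]
        - padded[size:, :-size]
        + padded[:-size, :-size]
    )
    rows, cols = np.nonzero(win == size * size)
    return np.stack([rows, cols], axis=1)


def extract_textons(
    img: RGBImage,
    mask: BinaryMask,
    label: str,
    n: int,
    seed: int,
    image_id: str = "image",
) -> list[Texton]:
    """Sample ``n`` 32×32 patches uniformly without replacement from the
    top-left positions whose window lies entirely inside the mask
    (``label='roi'``) or entirely outside it (``label='background'``)."""
    if label not in (ROI_LABEL, BACKGROUND_LABEL):
        raise ValueError(f"label must be {ROI_LABEL!r} or {BACKGROUND_LABEL!r}")
    if (mask.height, mask.width) != (img.height, img.width):
        raise ValueError("mask dimensions do not match image")
    allowed = mask.as_bool() if label == ROI_LABEL else ~mask.as_bool()
    positions = _valid_top_lefts(allowed)
    if positions.shape[0] == 0:
        raise ValueError(
            f"no {TEXTON_SIZE}x{TEXTON_SIZE} window fits entirely in the "
            f"{label} area; the region must span at least "
            f"{TEXTON_SIZE}x{TEXTON_SIZE} pixels"
        )
    if n > positions.shape[0]:
        raise ValueError(
            f"requested {n} textons but only {positions.shape[0]} valid "
            f"window positions exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(positions.shape[0], size=n, replace=False)
    out = []
    for r, c in positions[idx]:
        patch = img.data[r : r + TEXTON_SIZE, c : c + TEXTON_SIZE, :]
        out.append(Texton(patch=patch, source=(image_id, int(r), int(c)), label=label))
    return out


def _patch_opponents(patch: np.ndarray) -> np.ndarray:
    r, g, b = patch[:, :, 0], patch[:, :, 1], patch[:, :, 2]
    R = np.maximum(r - (g + b) / 2.0, 0.0)
    G = np.maximum(g - (r + b) / 2.0, 0.0)
    B = np.maximum(b - (r + g) / 2.0, 0.0)
    Y = np.maximum((r + g) / 2.0 - np.abs(r - g) / 2.0 - b, 0.0)
    return R + G + B + Y


def texton_features(
    texton: Texton | np.ndarray, bins: int = DEFAULT_ENTROPY_BINS
) -> FeatureVector:
    """(I, O, C, H) over the patch footprint.

    I: mean intensity; O: mean Gabor magnitude averaged over the four
    angles; C: mean summed color-opponency; H: Shannon entropy (bits) of
    the patch's ``bins``-level intensity histogram.
    """
    patch = texton.patch if isinstance(texton, Texton) else np.asarray(texton)
    intensity = patch.mean(axis=2)
    I = float(intensity.mean())
    O = float(
        np.mean([gabor_filter(intensity, theta).mean() for theta in GABOR_ANGLES_DEG])
    )
    C = float(_patch_opponents(patch).mean())
    quant = quantize_intensity(intensity, bins)
    counts = np.bincount(quant.ravel(), minlength=bins)
    p = counts[counts > 0] / quant.size
    H = float(-(p * np.log2(p)).sum())
    return FeatureVector(I=I, O=O, C=C, H=max(H, 0.0))


def raw_pixel_vector(texton: Texton | np.ndarray) -> np.ndarray:
    """Alternative feature mode: the flattened grayscale patch."""
    patch = texton.patch if isinstance(texton, Texton) else np.asarray(texton)
    return patch.mean(axis=2).ravel()


def build_database(
    textons: list[Texton],
    bins: int = DEFAULT_ENTROPY_BINS,
    feature_mode: str = "derived",
) -> TextonDatabase:
    """Fit a z-normalized exemplar database from labeled textons.

    Requires at least one exemplar per class; zero-variance dimensions
    are dropped from the metric with a warning.
    """
    if feature_mode not in ("derived", "raw"):
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    labels = []
    rows = []
    for t in textons:
        if t.label is None:
            raise ValueError("all textons must carry a training label")
        labels.append(t.label)
        if feature_mode == "derived":
            rows.append(texton_features(t, bins).as_array())
        else:
            rows.append(raw_pixel_vector(t))
    present = set(labels)
    if present != {ROI_LABEL, BACKGROUND_LABEL}:
        raise ValueError(
            f"database needs exemplars of both classes; got only {sorted(present)}"
        )
    vectors = np.asarray(rows, dtype=np.float64)
    mean = vectors.mean(axis=0)
    sd = vectors.std(axis=0)
    active = sd > 0
    if not active.all():
        logger.warning(
            "dropping %d constant feature dimension(s) from the kNN metric",
            int((~active).sum()),
        )
    if not active.any():
        raise ValueError("all feature dimensions are constant; kNN metric undefined")
    return TextonDatabase(
        vectors=vectors,
        labels=labels,
        mean=mean,
        sd=sd,
        active_dims=active,
        feature_mode=feature_mode,
    )


def knn_classify(
    v: FeatureVector | np.ndarray, db: TextonDatabase, k: int = DEFAULT_K
) -> tuple[str, float]:
    """Majority label among the k nearest exemplars (Euclidean distance
    in z-normalized space).

    Distance ties break by database insertion order; vote ties break
    toward background.
    """
    if k < 1 or k > len(db):
        raise ValueError(f"k={k} must be in [1, {len(db)}]")
    probe = v.as_array() if isinstance(v, FeatureVector) else np.asarray(v, dtype=np.float64)
    z_probe = db.transform(probe)
    act = db.active_dims
    z_db = (db.vectors[:, act] - db.mean[act]) / db.sd[act]
    dist = np.sqrt(((z_db - z_probe) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")[:k]
    votes = sum(1 for i in order if db.labels[i] == ROI_LABEL)
    label = ROI_LABEL if votes > k - votes else BACKGROUND_LABEL
    fraction = votes / k if label == ROI_LABEL else (k - votes) / k
    return label, fraction


def classify_region(
    region_id: int,
    regions: RegionMap,
    img: RGBImage,
    db: TextonDatabase,
    m: int = DEFAULT_TEXTONS_PER_REGION,
    k: int = DEFAULT_K,
    vote_threshold: float = DEFAULT_VOTE_THRESHOLD,
    seed: int = 0,
    bins: int = DEFAULT_ENTROPY_BINS,
) -> tuple[str, float]:
    """Classify one region by the fraction of its sampled textons the
    kNN labels roi.

    Windows are sampled uniformly without replacement from top-left
    corners whose 32×32 footprint lies inside the region's bounding box
    and whose center pixel belongs to the region.  Regions thinner than
    32 px in either bounding-box direction (or with no valid anchor)
    take the degenerate rule (background, 0.0).  Up to ``m`` windows are
    sampled, seeded per region so results do not depend on visit order.
    """
    inside = regions.labels == region_id
    rows, cols = np.nonzero(inside)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    if r1 - r0 + 1 < TEXTON_SIZE or c1 - c0 + 1 < TEXTON_SIZE:
        return BACKGROUND_LABEL, 0.0
    half = TEXTON_SIZE // 2
    # Top-left candidates: window in bbox, center pixel in the region.
    centers = inside[r0 + half : r1 - TEXTON_SIZE + half + 2, c0 + half : c1 - TEXTON_SIZE + half + 2]
    rr, cc = np.nonzero(centers)
    if rr.size == 0:
        return BACKGROUND_LABEL, 0.0
    positions = np.stack([rr + r0, cc + c0], axis=1)
    rng = np.random.default_rng([seed, region_id])
    n_take = min(m, positions.shape[0])
    idx = rng.choice(positions.shape[0], size=n_take, replace=False)
    roi_votes = 0
    for r, c in positions[idx]:
        patch = img.data[r : r + TEXTON_SIZE, c : c + TEXTON_SIZE, :]
        if db.feature_mode == "derived":
            probe: np.ndarray | FeatureVector = texton_features(patch, bins)
        else:
            probe = raw_pixel_vector(patch)
        label, _ = knn_classify(probe, db, k)
        if label == ROI_LABEL:
            roi_votes += 1
    fraction = roi_votes / n_take
    label = ROI_LABEL if fraction >= vote_threshold else BACKGROUND_LABEL
    return label, fraction


def find_first_target(
    summaries: list[RegionSummary],
    regions: RegionMap,
    img: RGBImage,
    db: TextonDatabase,
    m: int = DEFAULT_TEXTONS_PER_REGION,
    k: int = DEFAULT_K,
    vote_threshold: float = DEFAULT_VOTE_THRESHOLD,
    seed: int = 0,
    bins: int = DEFAULT_ENTROPY_BINS,
) -> SearchResult:
    """Walk regions in strictly decreasing attention order, classifying
    each until the first roi region is found."""
    if not summaries:
        raise ValueError("find_first_target requires at least one region summary")
    ordered = order_by_attention(summaries)
    examined: list[int] = []
    fractions: dict[int, float] = {}
    for s in ordered:
        examined.append(s.region_id)
        label, fraction = classify_region(
            s.region_id, regions, img, db, m=m, k=k,
            vote_threshold=vote_threshold, seed=seed, bins=bins,
        )
        fractions[s.region_id] = fraction
        if label == ROI_LABEL:
            return SearchResult(
                target_region_id=s.region_id,
                regions_examined=tuple(examined),
                vote_fractions=fractions,
            )
    return SearchResult(
        target_region_id=None,
        regions_examined=tuple(examined),
        vote_fractions=fractions,
    )
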