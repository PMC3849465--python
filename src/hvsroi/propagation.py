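"""Similarity-threshold propagation of the first detected target.

Once a target region is found, every other region whose feature distance
``df`` to the target falls under a threshold is accepted as an
additional region of interest.  ``df`` is the Euclidean distance between
per-region mean feature vectors (I, O, C, H), each dimension scaled by
its standard deviation across the image's regions so one threshold is
comparable across images and magnifications.  An unscaled variant and a
feature mask (e.g. to drop O) are available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from hvsroi.imaging_io import BinaryMask
from hvsroi.regions import RegionMap, RegionSummary

FEATURE_NAMES = ("I", "O", "C", "H")
#: In sd-scaled units.  Feature differences between tissue classes span
#: several per-image standard deviations, so a useful cutoff sits well
#: above 1.
DEFAULT_DF_THRESHOLD = 5.0


@dataclass(frozen=True)
class RoIResult:
    """Accepted regions (target first, then ascending df), the per-region
    distances, the threshold used, and the composed binary mask."""

    accepted_region_ids: tuple[int, ...]
    df_values: dict[int, float]
    threshold: float
    mask: BinaryMask | None = None


def feature_scales(
    summaries: list[RegionSummary], feature_mask: tuple[bool, bool, bool, bool] | None = None
) -> np.ndarray:
    """Per-dimension population standard deviation of (I, O, C, H)
    across the image's regions.

    Zero-variance dimensions get scale NaN, which drops them from the
    metric; a feature mask drops dimensions unconditionally.
    """
    mat = np.stack([s.feature_vector() for s in summaries])
    sd = mat.std(axis=0)
    sd[sd == 0] = np.nan
    if feature_mask is not None:
        sd[~np.asarray(feature_mask, dtype=bool)] = np.nan
    return sd


def feature_distance(
    s_t: RegionSummary,
    s_i: RegionSummary,
    scales: np.ndarray | None = None,
) -> float:
    """df = sqrt(Σ_f ((f_t − f_i) / scale_f)²) over f ∈ {I, O, C, H}.

    ``scales=None`` gives the unscaled variant (all scales 1); NaN scales
    mark dropped dimensions.
    """
    a = s_t.feature_vector()
    b = s_i.feature_vector()
    if scales is None:
        scales = np.ones(4)
    scales = np.asarray(scales, dtype=np.float64)
    keep = ~np.isnan(scales)
    if not keep.any():
        raise ValueError("all feature dimensions dropped; df undefined")
    if np.any(scales[keep] <= 0):
        raise ValueError("feature scales must be strictly positive")
    d = (a[keep] - b[keep]) / scales[keep]
    return float(np.sqrt((d * d).sum()))


def propagate(
    target_id: int,
    summaries: list[RegionSummary],
    threshold: float = DEFAULT_DF_THRESHOLD,
    scales: np.ndarray | None = None,
) -> RoIResult:
    """Accept the target plus every region with df(target, ·) ≤ threshold.

    The accepted list starts with the target and continues in ascending
    df (ties broken by region id); ``df_values`` records every region's
    distance.
    """
    by_id = {s.region_id: s for s in summaries}
    if target_id not in by_id:
        raise ValueError(f"target region {target_id} not present in summaries")
    target = by_id[target_id]
    df_values = {
        s.region_id: feature_distance(target, s, scales) for s in summaries
    }
    others = sorted(
        (
            s.region_id
            for s in summaries
            if s.region_id != target_id and df_values[s.region_id] <= threshold
        ),
        key=lambda rid: (df_values[rid], rid),
    )
    return RoIResult(
        accepted_region_ids=(target_id, *others),
        df_values=df_values,
        threshold=float(threshold),
    )


def compose_mask(regions: RegionMap, accepted_ids: tuple[int, ...] | list[int]) -> BinaryMask:
    """Binary mask that is 1 exactly on pixels of accepted regions."""
    accepted = np.asarray(sorted(set(int(i) for i in accepted_ids)), dtype=np.int64)
    if accepted.size == 0:
        raise ValueError("accepted_ids must not be empty")
    if accepted.min() < 1 or accepted.max() > regions.n_regions:
        bad = [int(i) for i in accepted if i < 1 or i > regions.n_regions]
        raise ValueError(f"unknown region id(s) {bad}")
    values = np.isin(regions.labels, accepted).astype(np.uint8)
    return BinaryMask(values)


def fill_mask(result: RoIResult, regions: RegionMap) -> RoIResult:
    """Return a copy of ``result`` with the composed mask attached."""
    return replace(result, mask=compose_mask(regions, result.accepted_region_ids))
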