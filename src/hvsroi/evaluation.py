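"""Pixel-level sensitivity/specificity evaluation and the end-to-end
pipeline runner.

``sensitivity = 100·TP/(TP+FN)`` and ``specificity = 100·TN/(TN+FP)``
are computed per image against a ground-truth mask; batch aggregates
report the mean and the *population* variance, both in percent (and
percent²).  Images whose ground truth has no positive (or no negative)
pixel have that metric reported as undefined and excluded from the
aggregates with a logged note.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

import hvsroi
from hvsroi.imaging_io import (
    BinaryMask,
    RGBImage,
    read_image,
    read_mask,
    to_intensity,
    write_mask,
)
from hvsroi.propagation import (
    DEFAULT_DF_THRESHOLD,
    RoIResult,
    feature_scales,
    fill_mask,
    propagate,
)
from hvsroi.regions import (
    DEFAULT_COMPACTNESS,
    DEFAULT_ENTROPY_BINS,
    DEFAULT_ENTROPY_WINDOW,
    DEFAULT_TARGET_REGIONS,
    EntropyMap,
    RegionMap,
    RegionSummary,
    attention_scores,
    local_entropy_map,
    segment_regions,
    summarize_regions,
)
from hvsroi.saliency import (
    SaliencyMap,
    combine_conspicuity,
    conspicuity_maps,
    resize_bilinear,
)
from hvsroi.search import (
    DEFAULT_K,
    DEFAULT_TEXTONS_PER_REGION,
    DEFAULT_VOTE_THRESHOLD,
    SearchResult,
    TextonDatabase,
    find_first_target,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """An error raised by one pipeline stage, tagged with its name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Every tunable of the four pipeline stages plus I/O paths.

    Serializes to/from YAML; unknown keys are rejected on load.
    """

    pyramid_levels: int = 9
    saliency_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    target_n: int = DEFAULT_TARGET_REGIONS
    compactness: float = DEFAULT_COMPACTNESS
    entropy_window: int = DEFAULT_ENTROPY_WINDOW
    entropy_bins: int = DEFAULT_ENTROPY_BINS
    attention_mode: str = "multiplicative"
    attention_gamma: float = 1.0
    k: int = DEFAULT_K
    m: int = DEFAULT_TEXTONS_PER_REGION
    vote_threshold: float = DEFAULT_VOTE_THRESHOLD
    df_threshold: float = DEFAULT_DF_THRESHOLD
    df_scaled: bool = True
    feature_mask: tuple[bool, bool, bool, bool] = (True, True, True, True)
    texton_feature_mode: str = "derived"
    seed: int = 0
    image_path: str | None = None
    db_path: str | None = None
    out_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("saliency_weights", "feature_mask"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class PipelineOutput:
    """Everything the four stages produce for one image."""

    saliency: SaliencyMap
    i_bar: np.ndarray
    c_bar: np.ndarray
    o_bar: np.ndarray
    entropy: EntropyMap
    regions: RegionMap
    summaries: list[RegionSummary]
    search: SearchResult
    roi: RoIResult | None
    mask: BinaryMask

    @property
    def no_target(self) -> bool:
        return self.search.target_region_id is None


def extract_rois(
    img: RGBImage, db: TextonDatabase, config: PipelineConfig | None = None
) -> PipelineOutput:
    """Run saliency → segmentation/entropy → search → propagation on one
    image, entirely in memory."""
    cfg = config or PipelineConfig()
    shape = (img.height, img.width)

    try:
        i_bar, c_bar, o_bar = conspicuity_maps(img, cfg.pyramid_levels)
        sal = combine_conspicuity(i_bar, c_bar, o_bar, shape, cfg.saliency_weights)
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise PipelineStageError("saliency", exc) from exc

    try:
        intensity = to_intensity(img)
        entropy = local_entropy_map(intensity, cfg.entropy_window, cfg.entropy_bins)
        regions = segment_regions(img, cfg.target_n, cfg.compactness)
        summaries = summarize_regions(
            regions,
            sal,
            intensity,
            resize_bilinear(o_bar, shape),
            resize_bilinear(c_bar, shape),
            entropy,
        )
        summaries = attention_scores(
            summaries, cfg.entropy_bins, cfg.attention_mode, cfg.attention_gamma
        )
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("region_fusion", exc) from exc

    try:
        search = find_first_target(
            summaries, regions, img, db,
            m=cfg.m, k=cfg.k, vote_threshold=cfg.vote_threshold,
            seed=cfg.seed, bins=cfg.entropy_bins,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("target_search", exc) from exc

    if search.target_region_id is None:
        logger.info("no target region found; emitting empty mask")
        empty = BinaryMask(np.zeros(shape, dtype=np.uint8))
        return PipelineOutput(
            saliency=sal, i_bar=i_bar, c_bar=c_bar, o_bar=o_bar,
            entropy=entropy, regions=regions, summaries=summaries,
            search=search, roi=None, mask=empty,
        )

    try:
        scales = (
            feature_scales(summaries, cfg.feature_mask) if cfg.df_scaled
            else np.where(np.asarray(cfg.feature_mask, dtype=bool), 1.0, np.nan)
        )
        roi = propagate(search.target_region_id, summaries, cfg.df_threshold, scales)
        roi = fill_mask(roi, regions)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("similarity_propagation", exc) from exc

    return PipelineOutput(
        saliency=sal, i_bar=i_bar, c_bar=c_bar, o_bar=o_bar,
        entropy=entropy, regions=regions, summaries=summaries,
        search=search, roi=roi, mask=roi.mask,
    )


def _write_heatmap(plane: np.ndarray, path: Path) -> None:
    lo, hi = float(plane.min()), float(plane.max())
    scaled = (plane - lo) / (hi - lo) if hi > lo else np.zeros_like(plane)
    Image.fromarray(np.round(scaled * 255).astype(np.uint8), mode="L").save(path)


def write_artifacts(out: PipelineOutput, cfg: PipelineConfig, out_dir: str | Path) -> None:
    """Write saliency/entropy heatmaps, label plane, summary tables, the
    RoI mask and a JSON run log."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    _write_heatmap(out.saliency.values, d / "saliency.png")
    np.save(d / "saliency.npy", out.saliency.values)
    _write_heatmap(out.entropy.values, d / "entropy.png")
    for name, plane in (("i_bar", out.i_bar), ("c_bar", out.c_bar), ("o_bar", out.o_bar)):
        _write_heatmap(plane, d / f"conspicuity_{name}.png")
    Image.fromarray(out.regions.labels.astype(np.uint16)).save(d / "regions.png")

    rows = ["region_id,area,I,O,C,H,mean_saliency,attention"]
    for s in sorted(out.summaries, key=lambda s: s.region_id):
        rows.append(
            f"{s.region_id},{s.area},{s.I:.10g},{s.O:.10g},{s.C:.10g},"
            f"{s.H:.10g},{s.mean_saliency:.10g},{s.attention:.10g}"
        )
    (d / "regions.csv").write_text("\n".join(rows) + "\n")

    write_mask(out.mask, d / "roi_mask.png")
    df_rows = ["region_id,df,accepted"]
    if out.roi is not None:
        accepted = set(out.roi.accepted_region_ids)
        for rid in sorted(out.roi.df_values):
            df_rows.append(
                f"{rid},{out.roi.df_values[rid]:.10g},{int(rid in accepted)}"
            )
    (d / "df.csv").write_text("\n".join(df_rows) + "\n")

    summary = {
        "config": dataclasses.asdict(cfg),
        "no_target": out.no_target,
        "target_region_id": out.search.target_region_id,
        "regions_examined": list(out.search.regions_examined),
        "accepted_region_ids": (
            list(out.roi.accepted_region_ids) if out.roi is not None else []
        ),
        "versions": {
            "python": platform.python_version(),
            "hvsroi": hvsroi.__version__,
            "numpy": np.__version__,
        },
    }
    (d / "run_summary.json").write_text(json.dumps(summary, indent=2))


def run_pipeline(config: PipelineConfig) -> PipelineOutput:
    """Disk-facing entry point: read image and database from the config
    paths, run :func:`extract_rois`, write artifacts to ``out_dir``."""
    if config.image_path is None or config.db_path is None:
        raise ValueError("config must set image_path and db_path")
    try:
        img = read_image(config.image_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("imaging_io", exc) from exc
    db = TextonDatabase.load(config.db_path)
    out = extract_rois(img, db, config)
    if config.out_dir is not None:
        write_artifacts(out, config, config.out_dir)
    return out


def sensitivity_specificity(
    pred: BinaryMask, gt: BinaryMask
) -> tuple[float | None, float | None]:
    """Pixel-level (sensitivity %, specificity %); a metric whose
    denominator is empty in the ground truth is returned as None."""
    if (pred.height, pred.width) != (gt.height, gt.width):
        raise ValueError(
            f"mask dimensions differ: pred {(pred.height, pred.width)} vs "
            f"gt {(gt.height, gt.width)}"
        )
    p = pred.as_bool()
    g = gt.as_bool()
    tp = int(np.sum(p & g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    fp = int(np.sum(p & ~g))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    if sens is None:
        logger.info("ground truth has no positive pixels; sensitivity undefined")
    if spec is None:
        logger.info("ground truth has no negative pixels; specificity undefined")
    return sens, spec


def region_level_sensitivity_specificity(
    pred: BinaryMask, gt: BinaryMask, regions: RegionMap
) -> tuple[float | None, float | None]:
    """Any-overlap region-level variant: a region counts positive if it
    overlaps the mask at all."""
    labels = regions.labels
    p = pred.as_bool()
    g = gt.as_bool()
    tp = fn = tn = fp = 0
    for rid in range(1, regions.n_regions + 1):
        sel = labels == rid
        pred_pos = bool(p[sel].any())
        gt_pos = bool(g[sel].any())
        tp += pred_pos and gt_pos
        fn += (not pred_pos) and gt_pos
        fp += pred_pos and (not gt_pos)
        tn += (not pred_pos) and (not gt_pos)
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return sens, spec


@dataclass(frozen=True)
class EvalResult:
    """Per-image metrics plus mean and population variance, in percent
    (and percent²); undefined per-image metrics are None and excluded
    from aggregates."""

    sensitivities: tuple[float | None, ...]
    specificities: tuple[float | None, ...]
    mean_sensitivity: float | None
    var_sensitivity: float | None
    mean_specificity: float | None
    var_specificity: float | None


def _aggregate(values: tuple[float | None, ...]) -> tuple[float | None, float | None]:
    defined = [v for v in values if v is not None]
    if not defined:
        return None, None
    arr = np.asarray(defined, dtype=np.float64)
    return float(arr.mean()), float(arr.var())


def evaluate_batch(pairs: list[tuple[BinaryMask, BinaryMask]]) -> EvalResult:
    """Aggregate pixel-level metrics over (pred, gt) mask pairs."""
    sens_list = []
    spec_list = []
    for pred, gt in pairs:
        sens, spec = sensitivity_specificity(pred, gt)
        sens_list.append(sens)
        spec_list.append(spec)
    mean_sens, var_sens = _aggregate(tuple(sens_list))
    mean_spec, var_spec = _aggregate(tuple(spec_list))
    return EvalResult(
        sensitivities=tuple(sens_list),
        specificities=tuple(spec_list),
        mean_sensitivity=mean_sens,
        var_sensitivity=var_sens,
        mean_specificity=mean_spec,
        var_specificity=var_spec,
    )


def frozen_suite_config(seed: int = 7) -> PipelineConfig:
    """Configuration frozen for the synthetic ``mag10`` regression suite
    (256×256 images, 160 target regions, df threshold 5.0)."""
    return PipelineConfig(target_n=160, df_threshold=5.0, seed=seed)


def run_synthetic_suite(
    n_test: int = 20,
    n_train: int = 1,
    textons_per_class: int = 50,
    base_seed: int = 7,
    config: PipelineConfig | None = None,
    preset_name: str = "mag10",
) -> EvalResult:
    """Train a texton database on synthetic fixtures and evaluate the
    full pipeline on a disjoint synthetic test set (pixel metrics)."""
    from hvsroi.fixtures import generate_test_set, generate_training_set, preset
    from hvsroi.search import build_database

    cfg = config or frozen_suite_config(base_seed)
    spec = preset(preset_name)
    _, textons, _ = generate_training_set(spec, n_train, textons_per_class, base_seed)
    db = build_database(textons)
    pairs = []
    for img, gt in generate_test_set(spec, n_test, base_seed):
        out = extract_rois(img, db, cfg)
        pairs.append((out.mask, gt))
    return evaluate_batch(pairs)


def evaluate_mask_files(
    pred_paths: list[str | Path], gt_paths: list[str | Path]
) -> EvalResult:
    """File-pair wrapper around :func:`evaluate_batch`; mismatched lists
    raise with the unpaired names."""
    pred_names = {Path(p).stem.replace("_pred", ""): Path(p) for p in pred_paths}
    gt_names = {Path(p).stem.replace("_mask", "").replace("_gt", ""): Path(p) for p in gt_paths}
    unpaired = sorted(set(pred_names) ^ set(gt_names))
    if unpaired:
        raise ValueError(f"unpaired mask files: {unpaired}")
    pairs = [
        (read_mask(pred_names[name]), read_mask(gt_names[name]))
        for name in sorted(pred_names)
    ]
    return evaluate_batch(pairs)
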