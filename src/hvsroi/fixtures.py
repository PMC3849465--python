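"""Seeded generator of histology-like fixture images with ground truth.

Images contain two visually distinct tissue classes: smooth random blobs
of a high-entropy basophilic ("carcinoma-like") texture — a bluish base
densely packed with dark elliptical nuclei and speckle — on a
lower-entropy eosinophilic ("stroma-like") background of smooth pink
fibrous texture.  Generation is bit-identical for a fixed spec, so the
fixtures double as frozen regression inputs for the end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from hvsroi.imaging_io import BinaryMask, RGBImage, write_image, write_mask
from hvsroi.search import BACKGROUND_LABEL, ROI_LABEL, Texton, extract_textons

#: Added to training base seeds to derive test-set seeds, so the two
#: seed ranges are disjoint by construction.
TEST_SEED_OFFSET = 1_000_000


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic field-of-view image."""

    height: int = 256
    width: int = 256
    n_roi_blobs: int = 2
    blob_radius_range: tuple[float, float] = (24.0, 48.0)
    nucleus_density: float = 0.02
    nucleus_radius_range: tuple[float, float] = (2.0, 4.0)
    roi_base_color: tuple[float, float, float] = (0.58, 0.46, 0.76)
    nucleus_color: tuple[float, float, float] = (0.26, 0.20, 0.48)
    roi_speckle: float = 0.10
    bg_color: tuple[float, float, float] = (0.92, 0.76, 0.83)
    fiber_density: float = 0.0008
    fiber_contrast: float = 0.05
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for c in (*self.roi_base_color, *self.nucleus_color, *self.bg_color):
            if not 0.0 <= c <= 1.0:
                raise ValueError("colors must lie in [0, 1]")
        if self.nucleus_density < 0 or self.fiber_density < 0:
            raise ValueError("densities must be >= 0")

    @property
    def nominal_coverage(self) -> float:
        """Expected mask area fraction: n_blobs · π·E[R²] / (H·W)."""
        a, b = self.blob_radius_range
        mean_r2 = (a * a + a * b + b * b) / 3.0
        return self.n_roi_blobs * np.pi * mean_r2 / (self.height * self.width)


#: Magnification presets emulating ×4-×40 fields: structure scale grows
#: with magnification while nuclei per unit area fall.
PRESETS: dict[str, dict] = {
    "mag4": dict(n_roi_blobs=3, blob_radius_range=(16.0, 30.0),
                 nucleus_radius_range=(1.0, 2.0), nucleus_density=0.06),
    "mag10": dict(n_roi_blobs=2, blob_radius_range=(24.0, 48.0),
                  nucleus_radius_range=(2.0, 4.0), nucleus_density=0.02),
    "mag20": dict(n_roi_blobs=2, blob_radius_range=(36.0, 60.0),
                  nucleus_radius_range=(3.0, 6.0), nucleus_density=0.012),
    "mag40": dict(n_roi_blobs=1, blob_radius_range=(56.0, 88.0),
                  nucleus_radius_range=(5.0, 9.0), nucleus_density=0.006),
}


def preset(name: str, seed: int = 0, height: int = 256, width: int = 256) -> FixtureSpec:
    """A magnification preset spec (``mag4`` … ``mag40``)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return FixtureSpec(height=height, width=width, seed=seed, **PRESETS[name])


def _blob_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    harmonics: np.ndarray,
    phases: np.ndarray,
) -> np.ndarray:
    """Rasterize one smooth star-shaped blob: r(θ) = R·(1 + Σ aₖ sin(kθ+φₖ))."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    theta = np.arctan2(dy, dx)
    bound = radius * (
        1.0
        + sum(
            a * np.sin((k + 2) * theta + p)
            for k, (a, p) in enumerate(zip(harmonics, phases))
        )
    )
    return np.hypot(dy, dx) <= bound


def generate_image(spec: FixtureSpec) -> tuple[RGBImage, BinaryMask]:
    """Render one seeded fixture image and its ground-truth mask."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    r_lo, r_hi = spec.blob_radius_range
    margin = 1.3 * r_hi
    if spec.n_roi_blobs > 0 and 2 * margin >= min(h, w):
        raise ValueError(
            f"blobs cannot fit: max radius {r_hi} (margin {margin:.0f}) in a "
            f"{h}x{w} image"
        )

    mask = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []
    for _ in range(spec.n_roi_blobs):
        radius = rng.uniform(r_lo, r_hi)
        for _attempt in range(500):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all(
                np.hypot(cy - py, cx - px) >= 0.9 * (radius + pr)
                for py, px, pr in placed
            ):
                break
        else:
            raise ValueError(
                f"could not place {spec.n_roi_blobs} disjoint blobs of radius "
                f"up to {r_hi} in a {h}x{w} image"
            )
        harmonics = rng.uniform(0.0, 0.08, size=3)
        phases = rng.uniform(0.0, 2 * np.pi, size=3)
        mask |= _blob_mask((h, w), (cy, cx), radius, harmonics, phases)
        placed.append((cy, cx, radius))

    # Background: smooth pink base with faint fibrous streaks.
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.bg_color
    low = rng.normal(0.0, 1.0, size=(max(h // 16, 2), max(w // 16, 2)))
    low = gaussian_filter(low, sigma=1.5, mode="reflect")
    field_mod = np.kron(low, np.ones((16, 16)))[:h, :w]
    field_mod = gaussian_filter(field_mod, sigma=8.0, mode="reflect")
    scale = field_mod.std()
    if scale > 0:
        field_mod = field_mod / scale * 0.02
    img += field_mod[:, :, None]

    n_fibers = int(round(spec.fiber_density * h * w))
    fibers = np.zeros((h, w))
    for _ in range(n_fibers):
        fy, fx = rng.uniform(0, h), rng.uniform(0, w)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(20, 60)
        t = np.linspace(-length / 2, length / 2, int(length * 2))
        ys = np.clip((fy + t * np.sin(ang)).astype(int), 0, h - 1)
        xs = np.clip((fx + t * np.cos(ang)).astype(int), 0, w - 1)
        fibers[ys, xs] = 1.0
    fibers = gaussian_filter(fibers, sigma=1.2, mode="reflect")
    fmax = fibers.max()
    if fmax > 0:
        img -= (fibers / fmax * spec.fiber_contrast)[:, :, None]

    # RoI: basophilic base, dark nuclei, speckle (high local entropy).
    roi = np.empty_like(img)
    roi[:] = spec.roi_base_color
    area = int(mask.sum())
    if area:
        n_nuclei = int(round(spec.nucleus_density * area))
        my, mx = np.nonzero(mask)
        if n_nuclei and my.size:
            pick = rng.choice(my.size, size=n_nuclei, replace=True)
            n_lo, n_hi = spec.nucleus_radius_range
            for j in pick:
                cy, cx = my[j], mx[j]
                ry = rng.uniform(n_lo, n_hi)
                rx = rng.uniform(n_lo, n_hi)
                ang = rng.uniform(0, np.pi)
                r_ext = int(np.ceil(max(ry, rx))) + 1
                y0, y1 = max(cy - r_ext, 0), min(cy + r_ext + 1, h)
                x0, x1 = max(cx - r_ext, 0), min(cx + r_ext + 1, w)
                yy, xx = np.mgrid[y0:y1, x0:x1]
                dy, dx = yy - cy, xx - cx
                u = dy * np.cos(ang) + dx * np.sin(ang)
                v = -dy * np.sin(ang) + dx * np.cos(ang)
                ell = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
                sub = roi[y0:y1, x0:x1]
                sub[ell] = spec.nucleus_color
        speckle = rng.uniform(-spec.roi_speckle, spec.roi_speckle, size=(h, w))
        roi += speckle[:, :, None]
    img[mask] = roi[mask]

    img += rng.normal(0.0, spec.noise_sd, size=(h, w, 3))
    np.clip(img, 0.0, 1.0, out=img)
    return RGBImage(img), BinaryMask(mask.astype(np.uint8))


def generate_training_set(
    spec: FixtureSpec,
    n_images: int,
    textons_per_class: int,
    base_seed: int = 0,
) -> tuple[list[tuple[RGBImage, BinaryMask]], list[Texton], list[dict]]:
    """Seeded image+mask pairs with sampled textons and a manifest.

    Training image seeds are ``base_seed + i``; use
    :func:`generate_test_set` for evaluation images — its seeds are
    offset by :data:`TEST_SEED_OFFSET` so the sets are disjoint.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    pairs: list[tuple[RGBImage, BinaryMask]] = []
    textons: list[Texton] = []
    manifest: list[dict] = []
    for i in range(n_images):
        image_id = f"train_{i:03d}"
        img, mask = generate_image(replace(spec, seed=base_seed + i))
        pairs.append((img, mask))
        for label in (ROI_LABEL, BACKGROUND_LABEL):
            batch = extract_textons(
                img, mask, label, textons_per_class,
                seed=base_seed + i, image_id=image_id,
            )
            textons.extend(batch)
            manifest.extend(
                {"image_id": image_id, "row": t.source[1], "col": t.source[2],
                 "label": label}
                for t in batch
            )
    return pairs, textons, manifest


def generate_test_set(
    spec: FixtureSpec, n_images: int, base_seed: int = 0
) -> list[tuple[RGBImage, BinaryMask]]:
    """Evaluation image+mask pairs with seeds disjoint from training."""
    return [
        generate_image(replace(spec, seed=TEST_SEED_OFFSET + base_seed + i))
        for i in range(n_images)
    ]


def write_fixture_suite(
    out_dir: str | Path,
    spec: FixtureSpec,
    n_train: int,
    n_test: int,
    textons_per_class: int,
    base_seed: int = 0,
) -> dict:
    """Write train/test images, masks and the texton manifest to disk."""
    out = Path(out_dir)
    (out / "train").mkdir(parents=True, exist_ok=True)
    (out / "test").mkdir(parents=True, exist_ok=True)
    pairs, _, manifest = generate_training_set(
        spec, n_train, textons_per_class, base_seed
    )
    for i, (img, mask) in enumerate(pairs):
        write_image(img, out / "train" / f"train_{i:03d}.png")
        write_mask(mask, out / "train" / f"train_{i:03d}_mask.png")
    lines = ["image_id,row,col,label"]
    lines += [f"{m['image_id']},{m['row']},{m['col']},{m['label']}" for m in manifest]
    (out / "train" / "textons.csv").write_text("\n".join(lines) + "\n")
    for i, (img, mask) in enumerate(generate_test_set(spec, n_test, base_seed)):
        write_image(img, out / "test" / f"test_{i:03d}.png")
        write_mask(mask, out / "test" / f"test_{i:03d}_mask.png")
    return {"n_train": n_train, "n_test": n_test, "manifest_rows": len(manifest)}
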