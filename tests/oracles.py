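"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written as plain loops against the documented
conventions, deliberately avoiding the package's vectorized code paths.
"""

import numpy as np


def bilinear_resize_oracle(plane: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Align-corners bilinear resampling via explicit per-pixel loops."""
    H, W = plane.shape
    h, w = shape
    out = np.empty((h, w))
    for i in range(h):
        y = 0.0 if h == 1 else i * (H - 1) / (h - 1)
        y0 = int(np.floor(y))
        y1 = min(y0 + 1, H - 1)
        fy = y - y0
        for j in range(w):
            x = 0.0 if w == 1 else j * (W - 1) / (w - 1)
            x0 = int(np.floor(x))
            x1 = min(x0 + 1, W - 1)
            fx = x - x0
            out[i, j] = (
                plane[y0, x0] * (1 - fy) * (1 - fx)
                + plane[y0, x1] * (1 - fy) * fx
                + plane[y1, x0] * fy * (1 - fx)
                + plane[y1, x1] * fy * fx
            )
    return out


def center_surround_oracle(pyr, c: int, s: int) -> np.ndarray:
    """|center − upsampled surround| using the loop-based resizer."""
    center = np.asarray(pyr[c])
    surround = bilinear_resize_oracle(np.asarray(pyr[s]), center.shape)
    return np.abs(center - surround)


def local_maxima_oracle(plane: np.ndarray) -> list[float]:
    """Strict 8-neighborhood local maxima by exhaustive scan; equal-valued
    plateaus are merged by flood fill and count once."""
    h, w = plane.shape
    visited = np.zeros((h, w), dtype=bool)
    values = []
    for i in range(h):
        for j in range(w):
            if visited[i, j]:
                continue
            # Flood-fill the plateau of equal value containing (i, j).
            v = plane[i, j]
            stack = [(i, j)]
            plateau = []
            seen = set()
            while stack:
                y, x = stack.pop()
                if (y, x) in seen:
                    continue
                seen.add((y, x))
                plateau.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and (ny, nx) not in seen:
                            if plane[ny, nx] == v:
                                stack.append((ny, nx))
            is_max = True
            for y, x in plateau:
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and (ny, nx) not in seen:
                            if plane[ny, nx] >= v:
                                is_max = False
            for y, x in plateau:
                visited[y, x] = True
            if is_max:
                values.append(v)
    return values


def normalize_map_oracle(plane: np.ndarray) -> np.ndarray:
    """Two-pass promotion oracle: rescale, exhaustively find maxima,
    apply the (M − m̄)² multiplier."""
    lo, hi = plane.min(), plane.max()
    if hi == lo:
        return np.zeros_like(plane)
    scaled = (plane - lo) / (hi - lo)
    maxima = sorted(local_maxima_oracle(scaled), reverse=True)
    others = maxima[1:]
    m_bar = sum(others) / len(others) if others else 0.0
    return scaled * (1.0 - m_bar) ** 2


def sliding_entropy_oracle(
    intensity: np.ndarray, window: int, bins: int
) -> np.ndarray:
    """Per-window histogram entropy (bits) with reflected borders,
    computed pixel by pixel."""
    quant = np.minimum((intensity * bins).astype(int), bins - 1)
    pad = window // 2
    lo_pad, hi_pad = pad, window - 1 - pad
    padded = np.pad(quant, ((lo_pad, hi_pad), (lo_pad, hi_pad)), mode="symmetric")
    h, w = intensity.shape
    out = np.empty((h, w))
    n = window * window
    for i in range(h):
        for j in range(w):
            win = padded[i : i + window, j : j + window]
            counts = np.bincount(win.ravel(), minlength=bins)
            p = counts[counts > 0] / n
            out[i, j] = -(p * np.log2(p)).sum()
    return out


def knn_oracle(
    probe: np.ndarray,
    vectors: np.ndarray,
    mean: np.ndarray,
    sd: np.ndarray,
    active: np.ndarray,
    k: int,
) -> list[int]:
    """Exhaustive all-pairs distance sort; returns the k nearest indices
    with distance ties broken by insertion order."""
    dists = []
    for idx in range(vectors.shape[0]):
        acc = 0.0
        for d in range(vectors.shape[1]):
            if active[d]:
                a = (probe[d] - mean[d]) / sd[d]
                b = (vectors[idx, d] - mean[d]) / sd[d]
                acc += (a - b) ** 2
        dists.append((np.sqrt(acc), idx))
    dists.sort(key=lambda t: (t[0], t[1]))
    return [idx for _, idx in dists[:k]]


def df_oracle(a: np.ndarray, b: np.ndarray, scales: np.ndarray) -> float:
    """Direct scaled-Euclidean formula over the kept dimensions."""
    acc = 0.0
    for f in range(len(a)):
        if not np.isnan(scales[f]):
            acc += ((a[f] - b[f]) / scales[f]) ** 2
    return float(np.sqrt(acc))
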