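"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-implementations (shift-enumerated
sliding-window morphology, explicit least squares, per-interval
trapezoids) kept separate from the package so the two routes stay
independent.
"""

from __future__ import annotations

import numpy as np


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    """Pixel offsets of a flat disk footprint (same shape as skimage's)."""
    offs = []
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            if di * di + dj * dj <= radius * radius:
                offs.append((di, dj))
    return offs


def _sliding(img: np.ndarray, radius: int, reduce) -> np.ndarray:
    """Min or max over a disk window, borders reflected."""
    offs = disk_offsets(radius)
    p = np.pad(img, radius, mode="reflect")
    n, m = img.shape
    stack = np.stack([p[radius + di : radius + di + n, radius + dj : radius + dj + m] for di, dj in offs])
    return reduce(stack, axis=0)


def brute_opening(img: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening by a disk: erosion (min) then dilation (max)."""
    eroded = _sliding(img, radius, np.min)
    return _sliding(eroded, radius, np.max)


def brute_tophat(img: np.ndarray, radius: int) -> np.ndarray:
    return img - brute_opening(img, radius)


def ols_slope(t: np.ndarray, v: np.ndarray) -> float:
    """Closed-form least-squares slope: cov(t, v) / var(t)."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    tm, vm = t.mean(), v.mean()
    return float(((t - tm) * (v - vm)).sum() / ((t - tm) ** 2).sum())


def trapezoid_sum(t: np.ndarray, v: np.ndarray) -> float:
    """Per-interval trapezoid accumulation."""
    total = 0.0
    for i in range(len(t) - 1):
        total += 0.5 * (v[i] + v[i + 1]) * (t[i + 1] - t[i])
    return total


def flood_fill_labels(mask: np.ndarray) -> int:
    """Count 8-connected components by explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    count = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            x, y = a + da, b + db
                            if (
                                0 <= x < mask.shape[0]
                                and 0 <= y < mask.shape[1]
                                and mask[x, y]
                                and not seen[x, y]
                            ):
                                seen[x, y] = True
                                stack.append((x, y))
    return count
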