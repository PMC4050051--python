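"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own morphology/statistics code
paths: surface voxels are counted by explicit array shifts, flood fill
by a queue-based BFS, and ANOVA mean squares by direct sums of squares.
"""

from __future__ import annotations

from collections import deque

import numpy as np

_SHIFTS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def surface_count(mask: np.ndarray) -> int:
    """Number of mask voxels with >= 1 of the 6 neighbors outside."""
    padded = np.pad(mask, 1)
    interior = np.ones_like(padded, dtype=bool)
    for dz, dx, dy in _SHIFTS:
        interior &= np.roll(padded, (dz, dx, dy), axis=(0, 1, 2))
    interior &= padded
    return int(padded.sum() - interior.sum())


def surface_mask(mask: np.ndarray) -> np.ndarray:
    padded = np.pad(mask, 1)
    interior = np.ones_like(padded, dtype=bool)
    for dz, dx, dy in _SHIFTS:
        interior &= np.roll(padded, (dz, dx, dy), axis=(0, 1, 2))
    out = padded & ~interior
    return out[1:-1, 1:-1, 1:-1]


def flood_fill(seeds: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    """6-connected BFS flood fill of ``seeds`` inside ``allowed``."""
    out = np.zeros_like(allowed, dtype=bool)
    queue = deque(map(tuple, np.column_stack(np.nonzero(seeds & allowed))))
    for p in queue:
        out[p] = True
    shape = allowed.shape
    while queue:
        z, x, y = queue.popleft()
        for dz, dx, dy in _SHIFTS:
            q = (z + dz, x + dx, y + dy)
            if (0 <= q[0] < shape[0] and 0 <= q[1] < shape[1]
                    and 0 <= q[2] < shape[2] and allowed[q] and not out[q]):
                out[q] = True
                queue.append(q)
    return out


def digitized_sphere(radius: int, pad: int = 2) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    c = radius + pad
    z, x, y = np.ogrid[:n, :n, :n]
    return (z - c) ** 2 + (x - c) ** 2 + (y - c) ** 2 <= radius ** 2


def digitized_cylinder(radius: int, length: int = 40, pad: int = 2) -> np.ndarray:
    """Solid cylinder along the y axis."""
    n = 2 * (radius + pad) + 1
    c = radius + pad
    z, x = np.ogrid[:n, :n]
    disc = (z - c) ** 2 + (x - c) ** 2 <= radius ** 2
    return np.repeat(disc[:, :, None], length, axis=2)


def anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way mean squares by direct elementwise sums of squares."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    return (ss_rows / (n - 1), ss_cols / (k - 1),
            ss_err / ((n - 1) * (k - 1)))


def icc_a1(x: np.ndarray) -> float:
    """ICC(A,1) from the brute-force ANOVA table."""
    n, k = x.shape
    msr, msc, mse = anova_mean_squares(x)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am ** 2).sum() * (bm ** 2).sum()))
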