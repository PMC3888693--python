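"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible (explicit loops, textbook
formulas) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np


def midranks(values):
    """Ranks with ties replaced by their midrank (average of tied positions)."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_sort_oracle(x, y):
    """Spearman correlation = Pearson correlation of midranks."""
    rx, ry = midranks(x), midranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return num / (dx * dy)


def features_bruteforce(block, n_bins, value_range=None):
    """Plain-loop first-order features from a histogram of gray levels.

    Returns (mu, sigma, entropy_bits, skewness, excess_kurtosis); skewness
    and kurtosis are NaN for constant blocks.
    """
    flat = [float(v) for row in np.asarray(block) for v in row]
    if value_range is None:
        lo, hi = min(flat), max(flat)
    else:
        lo, hi = value_range
    if hi <= lo:
        levels = [lo]
        counts = [len(flat)]
    else:
        levels = [lo + (hi - lo) * k / (n_bins - 1) for k in range(n_bins)]
        counts = [0] * n_bins
        for v in flat:
            k = int(round((v - lo) / (hi - lo) * (n_bins - 1)))
            k = min(max(k, 0), n_bins - 1)
            counts[k] += 1
    N = len(flat)
    H = [c / N for c in counts]

    mu = sum(g * h for g, h in zip(levels, H))
    mu2 = sum((g - mu) ** 2 * h for g, h in zip(levels, H))
    mu3 = sum((g - mu) ** 3 * h for g, h in zip(levels, H))
    mu4 = sum((g - mu) ** 4 * h for g, h in zip(levels, H))
    entropy = -sum(h * math.log2(h) for h in H if h > 0)
    if mu2 <= 0:
        skew = kurt = float("nan")
    else:
        skew = mu3 / mu2**1.5
        kurt = mu4 / mu2**2 - 3.0
    return mu, math.sqrt(mu2), entropy, skew, kurt


def equalize_tiles_naive(img, tile_px):
    """Per-tile histogram equalization with NO inter-tile blending.

    The contrast oracle for CLAHE's interpolation step: each tile is mapped
    to [0, 1] through its own empirical CDF independently, which leaves step
    artifacts at tile boundaries that the blended version must not have.
    """
    img = np.asarray(img, dtype=float)
    out = np.empty_like(img)
    H, W = img.shape
    for r0 in range(0, H, tile_px):
        for c0 in range(0, W, tile_px):
            tile = img[r0 : r0 + tile_px, c0 : c0 + tile_px]
            flat = np.sort(tile.ravel())
            # empirical CDF value of each pixel within its tile
            idx = np.searchsorted(flat, tile.ravel(), side="right")
            out[r0 : r0 + tile_px, c0 : c0 + tile_px] = (idx / flat.size).reshape(tile.shape)
    return out


def quadratic_map_oracle(a, pts):
    """Monomial-by-monomial evaluation of the 12-parameter transform."""
    res = []
    for x, y in np.atleast_2d(pts):
        xp = a[0][0] * x * x + a[0][1] * x * y + a[0][2] * y * y + a[0][3] * x + a[0][4] * y + a[0][5]
        yp = a[1][0] * x * x + a[1][1] * x * y + a[1][2] * y * y + a[1][3] * x + a[1][4] * y + a[1][5]
        res.append((xp, yp))
    return np.asarray(res)


def normal_equations_fit(src, dst):
    """Quadratic-transform fit by explicitly solving the normal equations."""
    src = np.asarray(src, float)
    A = np.column_stack([
        src[:, 0] ** 2, src[:, 0] * src[:, 1], src[:, 1] ** 2,
        src[:, 0], src[:, 1], np.ones(len(src)),
    ])
    return np.linalg.solve(A.T @ A, A.T @ np.asarray(dst, float)).T
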