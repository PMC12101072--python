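"""Shared fixtures and independent brute-force oracles.

The oracle implementations here are deliberately naive (explicit loops,
integral images, closed forms) and independent of the package's production
code paths.
"""

from __future__ import annotations

import numpy as np
import pytest


def brute_force_inscribed_side(mask: np.ndarray) -> int:
    """Exhaustive largest-inscribed-square search via an integral image."""
    m = np.asarray(mask).astype(np.int64)
    h, w = m.shape
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    ii[1:, 1:] = m.cumsum(0).cumsum(1)
    for s in range(min(h, w), 0, -1):
        sums = ii[s:, s:] - ii[:-s, s:] - ii[s:, :-s] + ii[:-s, :-s]
        if (sums == s * s).any():
            return s
    return 0


def brute_force_rotational_average(amp2d: np.ndarray):
    """Double-loop ring averaging with half-up rounding; DC excluded."""
    amp2d = np.asarray(amp2d, dtype=float)
    n = amp2d.shape[0]
    c = n // 2
    nyq = n // 2
    sums = np.zeros(nyq + 1)
    counts = np.zeros(nyq + 1)
    for i in range(n):
        for j in range(n):
            d = np.sqrt((i - c) ** 2 + (j - c) ** 2)
            r = int(np.floor(d + 0.5))
            if 1 <= r <= nyq:
                sums[r] += amp2d[i, j]
                counts[r] += 1
    freqs = np.arange(1, nyq + 1)
    return freqs, sums[1:] / counts[1:]


def normal_equation_weights(basis_cols: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Explicit normal-equations least squares: w = (A'A)^-1 A'b."""
    a = np.asarray(basis_cols, dtype=float)
    b = np.asarray(target, dtype=float)
    return np.linalg.solve(a.T @ a, a.T @ b)


def iterative_fill_oracle(image: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Explicit-loop re-implementation of neighbour-mean repair."""
    img = np.asarray(image, dtype=float).copy()
    bad = np.asarray(bad).astype(bool).copy()
    h, w = img.shape
    while bad.any():
        progress = []
        for i in range(h):
            for j in range(w):
                if not bad[i, j]:
                    continue
                vals = []
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        ii, jj = i + di, j + dj
                        if 0 <= ii < h and 0 <= jj < w and not bad[ii, jj]:
                            vals.append(img[ii, jj])
                if vals:
                    progress.append((i, j, float(np.mean(vals))))
        if not progress:
            raise ValueError("unfillable region")
        for i, j, v in progress:
            img[i, j] = v
            bad[i, j] = False
    return img


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
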