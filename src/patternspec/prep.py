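"""Image preparation: dark-noise subtraction, exposure-stability QC,
saturated-pixel repair, normalization, and the saturating excitation
transform E = P / (P + 1)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ReceptorImage",
    "estimate_dark_noise",
    "check_exposure_stability",
    "repair_saturated_pixels",
    "normalize",
    "naka_rushton",
]

#: Exposure QC threshold: relative variation of per-frame means over any
#: three consecutive frames must not exceed this (strict inequality).
EXPOSURE_VARIATION_THRESHOLD = 0.005

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


@dataclass
class ReceptorImage:
    """Excitation raster with values in [0, 1)."""

    values: np.ndarray
    provenance: str = "grey_standard"  # or "scene_mean"
    repaired_pixels: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values >= 1):
            raise ValueError("excitation values must lie in [0, 1)")
        if self.repaired_pixels < 0:
            raise ValueError("repaired_pixels must be >= 0")
        if self.provenance not in ("grey_standard", "scene_mean"):
            raise ValueError("provenance must be grey_standard or scene_mean")


def estimate_dark_noise(dark_columns: np.ndarray) -> float:
    """Mean of pixels from sensor columns that receive no light."""
    dark = np.asarray(dark_columns, dtype=float)
    if dark.size == 0:
        raise ValueError("dark-column region is empty")
    return float(dark.mean())


def check_exposure_stability(
    frame_means: np.ndarray, threshold: float = EXPOSURE_VARIATION_THRESHOLD
) -> tuple[bool, float]:
    """QC on temporal lighting stability for one filter.

    For every window of three consecutive per-frame means, the relative
    variation is (max - min) / mean of the window.  Fails iff any window's
    variation strictly exceeds the threshold (default 0.5%).

    Returns (passed, max_variation).
    """
    means = np.asarray(frame_means, dtype=float)
    if means.ndim != 1 or len(means) < 3:
        raise ValueError("need at least 3 consecutive frame means")
    windows = np.lib.stride_tricks.sliding_window_view(means, 3)
    variation = (windows.max(axis=1) - windows.min(axis=1)) / windows.mean(axis=1)
    max_var = float(variation.max())
    return max_var <= threshold, max_var


def repair_saturated_pixels(
    image: np.ndarray, bad: np.ndarray, max_iter: int = 1000
) -> tuple[np.ndarray, int]:
    """Replace flagged pixels by the mean of their valid 8-neighbours.

    Clusters are filled iteratively: pixels repaired in one pass become
    valid donors in the next, so multi-pixel clusters fill inward from
    their boundary.  Unflagged pixels are returned bit-identical.

    Returns (repaired raster, number of repaired pixels).
    """
    img = np.asarray(image, dtype=float)
    bad = np.asarray(bad).astype(bool)
    if bad.shape != img.shape:
        raise ValueError("bad mask must match image shape")
    n_bad = int(bad.sum())
    if n_bad == 0:
        return img.copy(), 0
    work = img.copy()
    valid = ~bad
    remaining = bad.copy()
    for _ in range(max_iter):
        if not remaining.any():
            break
        sums = ndimage.convolve(
            np.where(valid, work, 0.0), _NEIGHBOR_KERNEL, mode="constant"
        )
        counts = ndimage.convolve(
            valid.astype(float), _NEIGHBOR_KERNEL, mode="constant"
        )
        fillable = remaining & (counts > 0)
        if not fillable.any():
            raise ValueError(
                "flagged region has no valid neighbour anywhere on its boundary"
            )
        work[fillable] = sums[fillable] / counts[fillable]
        valid |= fillable
        remaining &= ~fillable
    else:
        raise ValueError("saturated-pixel repair did not converge")
    return work, n_bad


def normalize(image: np.ndarray, reference_mean: float) -> np.ndarray:
    """Divide every pixel by a reference mean (grey standard or scene mean)."""
    if reference_mean <= 0:
        raise ValueError("reference_mean must be positive")
    return np.asarray(image, dtype=float) / reference_mean


def naka_rushton(
    image: np.ndarray,
    provenance: str = "grey_standard",
    repaired_pixels: int = 0,
) -> ReceptorImage:
    """Saturating excitation transform E = P / (P + 1), elementwise.

    Strictly increasing, mapping [0, inf) into [0, 1).  Negative input
    pixels are rejected.
    """
    p = np.asarray(image, dtype=float)
    if np.any(p < 0):
        raise ValueError("input pixels must be non-negative")
    e = p / (p + 1.0)
    return ReceptorImage(values=e, provenance=provenance, repaired_pixels=repaired_pixels)
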