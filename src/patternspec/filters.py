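"""Computational receptor filters.

A computational filter is a weighted sum of measured camera-filter
sensitivity curves chosen so the combined curve approximates a target
photoreceptor sensitivity; applying the same weights per pixel to the
multispectral stack yields the receptor-view image.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "SensitivityCurve",
    "FilterWeights",
    "MultispectralStack",
    "fit_computational_filter",
    "apply_filter_weights",
]


@dataclass(frozen=True)
class SensitivityCurve:
    """Spectral sensitivity on a wavelength grid (nm), values >= 0."""

    wavelengths: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)
        if wl.ndim != 1 or wl.shape != v.shape:
            raise ValueError("wavelengths and values must be matching 1-D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("sensitivities must be finite")

    def interpolate(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation onto a grid; zero outside the support."""
        return np.interp(grid, self.wavelengths, self.values, left=0.0, right=0.0)

    @classmethod
    def from_csv(cls, path: str | Path, name: str = "") -> "SensitivityCurve":
        data = np.genfromtxt(path, delimiter=",", names=True)
        return cls(
            np.asarray(data["wavelength_nm"], dtype=float),
            np.asarray(data["sensitivity"], dtype=float),
            name=name or Path(path).stem,
        )

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.wavelengths, self.values])
        np.savetxt(
            path, arr, delimiter=",", header="wavelength_nm,sensitivity", comments=""
        )


@dataclass
class FilterWeights:
    """Least-squares weights for a computational filter, with fit diagnostics."""

    weights: np.ndarray
    fit_rmse: float
    fit_r2: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "weights": self.weights.tolist(),
                    "fit_rmse": self.fit_rmse,
                    "fit_r2": self.fit_r2,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterWeights":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["weights"]), d["fit_rmse"], d["fit_r2"])


@dataclass
class MultispectralStack:
    """Co-registered per-filter rasters in sensor digital numbers.

    channels has shape (n_filters, h, w).  dark_columns holds sensor
    columns that receive no light, shape (n_filters, h, n_dark); their
    statistics drive dark-noise subtraction.  saturated flags pixels at the
    sensor maximum or at/below the dark level.
    """

    channels: np.ndarray
    filter_names: list[str]
    dark_columns: np.ndarray | None = None
    saturated: np.ndarray | None = None
    sensor_max: float = 65535.0
    grey_standard_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3:
            raise ValueError("channels must have shape (n_filters, h, w)")
        if len(self.filter_names) != self.channels.shape[0]:
            raise ValueError("filter_names length must match channel count")
        if self.saturated is None:
            self.saturated = np.zeros(self.channels.shape, dtype=bool)

    @property
    def n_filters(self) -> int:
        return self.channels.shape[0]


def _common_grid(curves: list[SensitivityCurve]) -> np.ndarray:
    """Finest common grid: union of sample points inside the overlap range."""
    lo = max(c.wavelengths[0] for c in curves)
    hi = min(c.wavelengths[-1] for c in curves)
    if lo >= hi:
        raise ValueError("curves have no overlapping wavelength range")
    pts = np.unique(np.concatenate([c.wavelengths for c in curves]))
    return pts[(pts >= lo) & (pts <= hi)]


def fit_computational_filter(
    basis: list[SensitivityCurve],
    target: SensitivityCurve,
    non_negative: bool = False,
    min_overlap: float = 0.5,
) -> FilterWeights:
    """Weights minimising the squared difference between the weighted basis
    sum and the target sensitivity across the common wavelength grid.

    Weights are unconstrained by default (``non_negative=True`` switches to
    NNLS).  A rank-deficient basis yields the minimum-norm solution with a
    warning.  Raises if the common grid covers less than ``min_overlap`` of
    the target's wavelength span.
    """
    if not basis:
        raise ValueError("basis must contain at least one curve")
    grid = _common_grid(list(basis) + [target])
    target_span = target.wavelengths[-1] - target.wavelengths[0]
    overlap = grid[-1] - grid[0]
    if target_span > 0 and overlap / target_span < min_overlap:
        raise ValueError(
            f"common wavelength grid covers only {overlap / target_span:.0%} "
            f"of the target support (< {min_overlap:.0%})"
        )
    a = np.column_stack([c.interpolate(grid) for c in basis])
    b = target.interpolate(grid)
    if non_negative:
        w, _ = nnls(a, b)
    else:
        w, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
        if rank < a.shape[1]:
            warnings.warn(
                "rank-deficient basis; returning minimum-norm weights",
                stacklevel=2,
            )
    resid = a @ w - b
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((b - b.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return FilterWeights(weights=w, fit_rmse=rmse, fit_r2=r2)


def apply_filter_weights(
    stack: MultispectralStack, fw: FilterWeights
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel weighted sum of the stack's channels.

    Returns (receptor raster, propagated saturation flags): a pixel is
    flagged when any channel with a nonzero weight is flagged there.
    """
    w = np.asarray(fw.weights, dtype=float)
    if len(w) != stack.n_filters:
        raise ValueError(
            f"weight count {len(w)} != channel count {stack.n_filters}"
        )
    out = np.tensordot(w, stack.channels, axes=(0, 0))
    active = w != 0
    if active.any():
        flags = stack.saturated[active].any(axis=0)
    else:
        flags = np.zeros(out.shape, dtype=bool)
    return out, flags
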