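"""Diagnostic rendering: per-image log-log spectrum fits and crop overlays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from patternspec.cropping import CropRegion
from patternspec.spectrum import RadialSpectrum, SlopeFit

__all__ = ["plot_spectrum_fit", "plot_crop_overlay"]


def plot_spectrum_fit(
    rs: RadialSpectrum, fit: SlopeFit, path: str | Path, title: str = ""
) -> None:
    """Rotationally averaged spectrum with the binned points and fitted line."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    keep = rs.amplitudes > 0
    ax.plot(
        np.log10(rs.freqs_cpi[keep]), np.log10(rs.amplitudes[keep]),
        ".", ms=2, color="0.6", label="radial average",
    )
    ax.plot(fit.bin_centers, fit.bin_means, "o", color="C0", label="bin means")
    xs = np.array([fit.bin_centers.min(), fit.bin_centers.max()])
    ax.plot(xs, fit.slope * xs + fit.intercept, "-", color="C3",
            label=f"slope {fit.slope:.2f} (R²={fit.r2:.2f})")
    ax.set_xlabel("log10 frequency (cycles/image)")
    ax.set_ylabel("log10 amplitude")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_crop_overlay(
    image: np.ndarray, crop: CropRegion, path: str | Path
) -> None:
    """Image with the analysis square drawn on top (visual QC)."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image, cmap="gray")
    ax.add_patch(
        plt.Rectangle(
            (crop.col0 - 0.5, crop.row0 - 0.5), crop.side_px, crop.side_px,
            edgecolor="y", facecolor="none", lw=1.5,
        )
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
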