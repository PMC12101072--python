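"""Spectral-slope measurement.

The measurement chain for one square image: raised-cosine edge taper,
centred 2-D FFT amplitude spectrum, rotational averaging into integer-radius
annuli, frequency-range selection (and optional cross-individual
harmonization in cycles/mm), log-spaced binning, and an ordinary
least-squares line fit in the log-log plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import tukey

__all__ = [
    "RadialSpectrum",
    "SlopeFit",
    "BinnedSpectrum",
    "cosine_taper",
    "amplitude_spectrum",
    "rotational_average",
    "select_frequency_range",
    "harmonize_species_range",
    "bin_log_spectrum",
    "fit_spectral_slope",
    "measure_slope",
]

#: Analysis-floor frequency in cycles/image and the crop-size divisor for
#: the analysis ceiling (f_hi = side_px // DEFAULT_MAX_FREQ_DIVISOR).
DEFAULT_MIN_FREQ_CPI = 5
DEFAULT_MAX_FREQ_DIVISOR = 10
DEFAULT_TAPER_FREQUENCY = 4
DEFAULT_N_BINS = 9


@dataclass
class RadialSpectrum:
    """Rotationally averaged amplitude vs integer radial frequency.

    freqs_cpi are cycles/image; when crop_mm (physical crop side in mm) is
    set, freqs_cpmm = freqs_cpi / crop_mm.
    """

    freqs_cpi: np.ndarray
    amplitudes: np.ndarray
    crop_mm: float | None = None

    def __post_init__(self) -> None:
        self.freqs_cpi = np.asarray(self.freqs_cpi)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.freqs_cpi.shape != self.amplitudes.shape:
            raise ValueError("freqs and amplitudes must have equal length")
        if np.any(np.diff(self.freqs_cpi) <= 0):
            raise ValueError("freqs_cpi must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def freqs_cpmm(self) -> np.ndarray:
        if self.crop_mm is None:
            raise ValueError("crop_mm calibration not set")
        return self.freqs_cpi / self.crop_mm

    def restrict(self, f_lo_cpi: float, f_hi_cpi: float) -> "RadialSpectrum":
        keep = (self.freqs_cpi >= f_lo_cpi) & (self.freqs_cpi <= f_hi_cpi)
        return RadialSpectrum(self.freqs_cpi[keep], self.amplitudes[keep], self.crop_mm)


@dataclass
class BinnedSpectrum:
    """Log-binned points actually entering the slope regression."""

    log10_freq: np.ndarray
    log10_amp: np.ndarray
    counts: np.ndarray
    n_bins_requested: int

    @property
    def n_bins_used(self) -> int:
        return len(self.log10_freq)


@dataclass
class SlopeFit:
    """OLS line fit of log10 amplitude on log10 frequency."""

    slope: float
    intercept: float
    r2: float
    f_lo_cpi: float
    f_hi_cpi: float
    n_bins: int
    bin_centers: np.ndarray = field(repr=False)
    bin_means: np.ndarray = field(repr=False)
    f_lo_cpmm: float | None = None
    f_hi_cpmm: float | None = None


def cosine_taper(
    image: np.ndarray, taper_frequency: float = DEFAULT_TAPER_FREQUENCY
) -> np.ndarray:
    """Blend the image toward its own mean at the borders.

    A separable raised-cosine (Tukey) window W is 1 in the interior and
    rolls off to 0 over a half-cosine of width side / (2 * taper_frequency)
    at each edge; the output is mean + W * (image - mean), so corner and
    edge pixels equal the pre-taper mean exactly and the taper's own
    spectral content stays below the analysis floor.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be a square 2-D raster")
    if taper_frequency <= 0:
        raise ValueError("taper_frequency must be positive")
    n = image.shape[0]
    rolloff = n / (2.0 * taper_frequency)
    if rolloff < 2:
        raise ValueError(
            f"taper roll-off width {rolloff:.2f} px < 2 px; image too small "
            f"for taper_frequency={taper_frequency}"
        )
    # tukey(alpha) rolls off over alpha*n/2 samples per edge
    w = tukey(n, alpha=1.0 / taper_frequency)
    window = np.outer(w, w)
    mean = image.mean()
    return mean + window * (image - mean)


def amplitude_spectrum(image: np.ndarray) -> np.ndarray:
    """Modulus of the centred 2-D DFT (DC at the grid centre, index N//2)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be a square 2-D raster")
    return np.abs(np.fft.fftshift(np.fft.fft2(image)))


def rotational_average(
    amp2d: np.ndarray, crop_mm: float | None = None
) -> RadialSpectrum:
    """Average a centred amplitude grid over integer-radius annuli.

    Each coefficient is assigned to the integer radius its Euclidean
    distance from DC rounds to (half-up).  DC itself and radii beyond
    Nyquist (N // 2) are excluded.
    """
    amp2d = np.asarray(amp2d, dtype=float)
    if amp2d.ndim != 2 or amp2d.shape[0] != amp2d.shape[1]:
        raise ValueError("amplitude grid must be square")
    n = amp2d.shape[0]
    c = n // 2  # DC index after fftshift
    idx = np.arange(n) - c
    dist = np.hypot(idx[:, None], idx[None, :])
    ring = np.floor(dist + 0.5).astype(int)  # half-up rounding
    nyquist = n // 2
    valid = (ring >= 1) & (ring <= nyquist)
    sums = np.bincount(ring[valid], weights=amp2d[valid], minlength=nyquist + 1)
    counts = np.bincount(ring[valid], minlength=nyquist + 1)
    freqs = np.arange(1, nyquist + 1)
    means = sums[1:] / counts[1:]
    return RadialSpectrum(freqs, means, crop_mm)


def select_frequency_range(
    side_px: int,
    min_freq_cpi: int = DEFAULT_MIN_FREQ_CPI,
    divisor: int = DEFAULT_MAX_FREQ_DIVISOR,
) -> tuple[int, int]:
    """Analysed frequency bounds in cycles/image for a crop of given side.

    Returns (min_freq_cpi, floor(side_px / divisor)).  Raises if the range
    holds fewer than two integer frequencies.
    """
    if side_px < 1:
        raise ValueError("side_px must be positive")
    f_lo = min_freq_cpi
    f_hi = side_px // divisor
    if f_hi - f_lo + 1 < 2:
        raise ValueError(
            f"side {side_px} px leaves fewer than 2 analysable frequencies "
            f"in [{f_lo}, {f_hi}]"
        )
    return f_lo, f_hi


def harmonize_species_range(
    members: list[tuple[int, int, float]],
    cap_cpmm: float | None = None,
    mode: str = "intent",
) -> tuple[float, float, list[tuple[int, int]]]:
    """Common physical frequency range for all individuals of one species.

    Parameters
    ----------
    members : list of (f_lo_cpi, f_hi_cpi, crop_mm) per individual image.
    cap_cpmm : optional ceiling in cycles/mm from the shortest-extension
        camera calibration (see acuity.max_analyzed_frequency).
    mode : "intent" (default) takes the common lower bound as the MAXIMUM
        of per-member minimum frequencies in cycles/mm, so every member can
        actually cover the shared range; "literal" takes the minimum, which
        excludes nothing.

    Returns
    -------
    (lo_cpmm, hi_cpmm, per_member_bounds) where per_member_bounds holds each
    member's analysed integer cycles/image range after harmonization.
    """
    if not members:
        raise ValueError("at least one member required")
    if mode not in ("intent", "literal"):
        raise ValueError("mode must be 'intent' or 'literal'")
    los = np.array([lo / mm for lo, _, mm in members], dtype=float)
    his = np.array([hi / mm for _, hi, mm in members], dtype=float)
    lo_cpmm = float(los.max() if mode == "intent" else los.min())
    hi_cpmm = float(his.min())
    if cap_cpmm is not None:
        hi_cpmm = min(hi_cpmm, cap_cpmm)
    if lo_cpmm >= hi_cpmm:
        raise ValueError("harmonized frequency range is empty")
    eps = 1e-9
    out = []
    for f_lo, f_hi, mm in members:
        lo_cpi = max(f_lo, int(np.ceil(lo_cpmm * mm - eps)))
        hi_cpi = min(f_hi, int(np.floor(hi_cpmm * mm + eps)))
        if hi_cpi - lo_cpi + 1 < 2:
            raise ValueError("harmonized range leaves fewer than 2 frequencies")
        out.append((lo_cpi, hi_cpi))
    return lo_cpmm, hi_cpmm, out


def bin_log_spectrum(
    rs: RadialSpectrum,
    f_lo: float,
    f_hi: float,
    n_bins: int = DEFAULT_N_BINS,
    x_mode: str = "mean_log",
) -> BinnedSpectrum:
    """Average amplitudes in bins evenly spaced in log10 frequency.

    Within each bin, y = log10(mean amplitude of members) and
    x = mean log10 frequency of members (x_mode="mean_log", default) or the
    bin's geometric centre (x_mode="geometric_center").  Empty bins are
    dropped with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    sub = rs.restrict(f_lo, f_hi)
    freqs = sub.freqs_cpi.astype(float)
    amps = sub.amplitudes
    if len(freqs) < 2:
        raise ValueError("fewer than 2 frequencies in the analysed range")
    edges = np.logspace(np.log10(f_lo), np.log10(f_hi), n_bins + 1)
    which = np.clip(np.searchsorted(edges, freqs, side="right") - 1, 0, n_bins - 1)
    xs, ys, counts = [], [], []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        if x_mode == "mean_log":
            xs.append(np.log10(freqs[sel]).mean())
        elif x_mode == "geometric_center":
            xs.append((np.log10(edges[b]) + np.log10(edges[b + 1])) / 2.0)
        else:
            raise ValueError("x_mode must be 'mean_log' or 'geometric_center'")
        ys.append(np.log10(amps[sel].mean()))
        counts.append(int(sel.sum()))
    if len(xs) < 2:
        raise ValueError("fewer than 2 non-empty bins")
    if len(xs) < n_bins:
        warnings.warn(
            f"only {len(xs)} of {n_bins} bins are non-empty", stacklevel=2
        )
    return BinnedSpectrum(np.array(xs), np.array(ys), np.array(counts), n_bins)


def fit_spectral_slope(
    binned: BinnedSpectrum,
    f_lo_cpi: float | None = None,
    f_hi_cpi: float | None = None,
    crop_mm: float | None = None,
) -> SlopeFit:
    """OLS fit of log10 amplitude on log10 frequency over the binned points."""
    x, y = binned.log10_freq, binned.log10_amp
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log-frequency")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    lo = float(f_lo_cpi) if f_lo_cpi is not None else float(10 ** x.min())
    hi = float(f_hi_cpi) if f_hi_cpi is not None else float(10 ** x.max())
    return SlopeFit(
        slope=float(slope),
        intercept=float(intercept),
        r2=r2,
        f_lo_cpi=lo,
        f_hi_cpi=hi,
        n_bins=binned.n_bins_used,
        bin_centers=x.copy(),
        bin_means=y.copy(),
        f_lo_cpmm=lo / crop_mm if crop_mm else None,
        f_hi_cpmm=hi / crop_mm if crop_mm else None,
    )


def measure_slope(
    image: np.ndarray,
    crop_mm: float | None = None,
    taper_frequency: float | None = DEFAULT_TAPER_FREQUENCY,
    n_bins: int = DEFAULT_N_BINS,
    f_range_cpi: tuple[int, int] | None = None,
    min_freq_cpi: int = DEFAULT_MIN_FREQ_CPI,
    divisor: int = DEFAULT_MAX_FREQ_DIVISOR,
) -> SlopeFit:
    """Full single-image measurement: taper -> FFT -> radial average ->
    range select -> bin -> fit.

    f_range_cpi overrides the default size-based rule (used after species
    harmonization).  taper_frequency=None skips the taper.
    """
    img = np.asarray(image, dtype=float)
    if taper_frequency is not None:
        img = cosine_taper(img, taper_frequency)
    amp = amplitude_spectrum(img)
    rs = rotational_average(amp, crop_mm=crop_mm)
    if f_range_cpi is None:
        f_range_cpi = select_frequency_range(img.shape[0], min_freq_cpi, divisor)
    f_lo, f_hi = f_range_cpi
    binned = bin_log_spectrum(rs, f_lo, f_hi, n_bins=n_bins)
    return fit_spectral_slope(binned, f_lo, f_hi, crop_mm)
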