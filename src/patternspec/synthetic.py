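"""Synthetic inputs with known ground truth.

Everything the measurement pipeline consumes can be generated here:
power-law images of chosen spectral slope (the oracle for the spectrum
module), abdomen-shaped masks, multispectral stacks with known filter
curves, dark offset and saturated pixels, and hierarchically structured
cohorts of per-specimen slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from patternspec.filters import MultispectralStack, SensitivityCurve

__all__ = [
    "PowerLawSpec",
    "SyntheticCohortSpec",
    "gen_powerlaw_image",
    "gen_abdomen_mask",
    "ellipse_mask",
    "fan_mask",
    "gen_multispectral_stack",
    "gen_cohort",
    "make_filter_bank",
    "make_receptor_curve",
]


@dataclass(frozen=True)
class PowerLawSpec:
    """Target for power-law image synthesis.

    The 2-D amplitude spectrum is proportional to f**beta (radial frequency
    f in cycles/image); contrast is the RMS amplitude around mean_level.
    """

    beta: float
    size_px: int = 512
    mean_level: float = 0.5
    contrast: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_px < 64:
            raise ValueError("size_px must be >= 64")
        if not 0 < self.mean_level < 1:
            raise ValueError("mean_level must lie in (0, 1)")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")


def gen_powerlaw_image(spec: PowerLawSpec) -> np.ndarray:
    """Real-valued raster whose amplitude spectrum follows f**beta.

    Phases are uniform random with Hermitian symmetry (obtained from the
    FFT of white noise, which guarantees a real inverse transform); the DC
    coefficient is zeroed and the requested mean added afterwards, so the
    mean is exact.  Values are clipped to [0, 1] and the clipped fraction
    checked: more than 5% clipping is rejected as a spectral distortion.
    """
    n = spec.size_px
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal((n, n))
    phases = np.fft.fft2(white)
    mod = np.abs(phases)
    mod[mod == 0] = 1.0
    phases = phases / mod

    f = np.hypot(*np.meshgrid(np.fft.fftfreq(n) * n, np.fft.fftfreq(n) * n))
    with np.errstate(divide="ignore"):
        amp = np.where(f > 0, f**spec.beta, 0.0)
    img = np.fft.ifft2(amp * phases).real
    sd = img.std()
    if sd > 0:
        img *= spec.contrast / sd
    img += spec.mean_level

    clipped = float(np.mean((img < 0) | (img > 1)))
    if clipped > 0.05:
        raise ValueError(
            f"contrast {spec.contrast} clips {clipped:.1%} of pixels (> 5%); "
            "reduce contrast or adjust mean_level"
        )
    return np.clip(img, 0.0, 1.0)


def ellipse_mask(
    size_px: int,
    center: tuple[float, float] | None = None,
    semi_axes: tuple[float, float] | None = None,
) -> np.ndarray:
    """Filled ellipse; defaults to a centred ellipse with axes 0.4/0.3 of size."""
    if center is None:
        center = ((size_px - 1) / 2.0, (size_px - 1) / 2.0)
    if semi_axes is None:
        semi_axes = (0.4 * size_px, 0.3 * size_px)
    rr, cc = np.mgrid[0:size_px, 0:size_px]
    a, b = semi_axes
    return ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0


def fan_mask(
    size_px: int,
    radius: float,
    half_angle_deg: float = 100.0,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Filled fan: circular sector opening downward from its apex."""
    if center is None:
        center = (0.25 * size_px, (size_px - 1) / 2.0)
    rr, cc = np.mgrid[0:size_px, 0:size_px]
    dr, dc = rr - center[0], cc - center[1]
    dist = np.hypot(dr, dc)
    # angle from the downward axis
    ang = np.degrees(np.abs(np.arctan2(dc, dr)))
    return (dist <= radius) & (ang <= half_angle_deg)


def gen_abdomen_mask(size_px: int, shape: str = "ellipse", seed: int = 0) -> np.ndarray:
    """Abdomen-like binary mask: a single connected region filling 20-80%.

    shape="ellipse" gives a randomly elongated centred ellipse; "fan" a
    circular sector (the male fan silhouette).
    """
    if size_px < 64:
        raise ValueError("size_px must be >= 64")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.03, 0.03, size=2) * size_px
    if shape == "ellipse":
        a = rng.uniform(0.30, 0.44) * size_px
        b = rng.uniform(0.30, 0.44) * size_px
        c = ((size_px - 1) / 2.0 + jitter[0], (size_px - 1) / 2.0 + jitter[1])
        return ellipse_mask(size_px, center=c, semi_axes=(a, b))
    if shape == "fan":
        radius = rng.uniform(0.55, 0.70) * size_px
        half_angle = rng.uniform(80.0, 110.0)
        c = (0.18 * size_px + jitter[0], (size_px - 1) / 2.0 + jitter[1])
        return fan_mask(size_px, radius=radius, half_angle_deg=half_angle, center=c)
    raise ValueError("shape must be 'ellipse' or 'fan'")


def make_filter_bank(
    n_filters: int = 5,
    wavelengths: np.ndarray | None = None,
    peaks: np.ndarray | None = None,
    width_nm: float = 45.0,
) -> list[SensitivityCurve]:
    """Gaussian band-pass camera filter curves on a common grid (nm)."""
    if wavelengths is None:
        wavelengths = np.arange(300.0, 701.0, 2.0)
    if peaks is None:
        peaks = np.linspace(360.0, 640.0, n_filters)
    return [
        SensitivityCurve(
            wavelengths,
            np.exp(-0.5 * ((wavelengths - p) / width_nm) ** 2),
            name=f"filter_{i}",
        )
        for i, p in enumerate(peaks)
    ]


def make_receptor_curve(
    peak_nm: float = 530.0,
    width_nm: float = 55.0,
    wavelengths: np.ndarray | None = None,
) -> SensitivityCurve:
    """Gaussian stand-in for a photoreceptor spectral sensitivity."""
    if wavelengths is None:
        wavelengths = np.arange(300.0, 701.0, 2.0)
    return SensitivityCurve(
        wavelengths,
        np.exp(-0.5 * ((wavelengths - peak_nm) / width_nm) ** 2),
        name=f"receptor_{peak_nm:.0f}nm",
    )


def gen_multispectral_stack(
    scene: np.ndarray,
    filter_curves: list[SensitivityCurve],
    reflectance: SensitivityCurve,
    dark_offset: float = 250.0,
    saturate_fraction: float = 0.0,
    seed: int = 0,
    read_noise_sd: float = 0.0,
    gain: float | None = None,
    n_dark_cols: int = 16,
    sensor_max: float = 65535.0,
    grey_standard_mask: np.ndarray | None = None,
) -> MultispectralStack:
    """Forward-model a multispectral capture of a scene.

    Each channel is the scene (relative radiance in [0, 1]) scaled by the
    inner product of the reflectance spectrum with that filter curve, times
    a gain, plus the dark offset and Gaussian read noise.  A stated
    fraction of pixels is forced to the sensor maximum; dark columns are
    recorded alongside the channels.
    """
    scene = np.asarray(scene, dtype=float)
    if scene.ndim != 2:
        raise ValueError("scene must be a 2-D raster")
    grids = {tuple(c.wavelengths.tolist()) for c in filter_curves}
    if len(grids) != 1:
        raise ValueError("filter curves must share a common wavelength grid")
    wl = filter_curves[0].wavelengths
    refl = reflectance.interpolate(wl)
    dots = np.array(
        [np.trapezoid(refl * c.values, wl) for c in filter_curves], dtype=float
    )
    if gain is None:
        gain = 0.8 * (sensor_max - dark_offset) / max(dots.max(), 1e-12)

    rng = np.random.default_rng(seed)
    h, w = scene.shape
    channels = dark_offset + gain * dots[:, None, None] * scene[None, :, :]
    if read_noise_sd > 0:
        channels = channels + rng.normal(0.0, read_noise_sd, size=channels.shape)
    channels = np.clip(channels, 0.0, sensor_max)

    if not 0 <= saturate_fraction < 1:
        raise ValueError("saturate_fraction must lie in [0, 1)")
    n_sat = int(round(saturate_fraction * h * w))
    if n_sat > 0:
        flat = rng.choice(h * w, size=n_sat, replace=False)
        rr, cc = np.unravel_index(flat, (h, w))
        channels[:, rr, cc] = sensor_max

    dark = dark_offset + (
        rng.normal(0.0, read_noise_sd, size=(len(filter_curves), h, n_dark_cols))
        if read_noise_sd > 0
        else np.zeros((len(filter_curves), h, n_dark_cols))
    )
    saturated = channels >= sensor_max
    return MultispectralStack(
        channels=channels,
        filter_names=[c.name for c in filter_curves],
        dark_columns=dark,
        saturated=saturated,
        sensor_max=sensor_max,
        grey_standard_mask=grey_standard_mask,
    )


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Hierarchical generator for per-specimen slopes.

    Spider slopes follow
        slope = mu_female + delta_sex * male + a_species + b_species * male + eps
    with species effects (a, b) ~ Normal(0, sd_species / sd_species_sex)
    and residual Normal(0, sd_resid).  Scene slopes are
    Normal(mu_scene, sd_scene), split over two regions.

    Defaults mirror the summary statistics of the study system the package
    was built for, so demo runs look realistic; they carry no validation
    weight.
    """

    n_species: int = 18
    n_per_sex: int = 5
    mu_female: float = -1.17
    delta_sex: float = -0.31
    sd_species: float = 0.10
    sd_species_sex: float = 0.10
    sd_resid: float = 0.10
    mu_scene: float = -1.09
    sd_scene: float = 0.14
    n_scenes: int = 41
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_per_sex, self.n_scenes) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.sd_species, self.sd_species_sex, self.sd_resid, self.sd_scene) < 0:
            raise ValueError("standard deviations must be >= 0")


def gen_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Cohort table with columns unit_id, group, species, sex, region, slope."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    a = rng.normal(0.0, spec.sd_species, size=spec.n_species)
    b = rng.normal(0.0, spec.sd_species_sex, size=spec.n_species)
    for j in range(spec.n_species):
        for sex, male in (("female", 0), ("male", 1)):
            eps = rng.normal(0.0, spec.sd_resid, size=spec.n_per_sex)
            slopes = spec.mu_female + spec.delta_sex * male + a[j] + b[j] * male + eps
            for k, s in enumerate(slopes):
                rows.append(
                    {
                        "unit_id": f"sp{j:02d}_{sex}_{k}",
                        "group": "spider",
                        "species": f"species_{j:02d}",
                        "sex": sex,
                        "region": "",
                        "slope": float(s),
                    }
                )
    scene_slopes = rng.normal(spec.mu_scene, spec.sd_scene, size=spec.n_scenes)
    for k, s in enumerate(scene_slopes):
        rows.append(
            {
                "unit_id": f"scene_{k:02d}",
                "group": "scene",
                "species": "",
                "sex": "",
                "region": "region_1" if k % 2 == 0 else "region_2",
                "slope": float(s),
            }
        )
    return pd.DataFrame(rows)
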