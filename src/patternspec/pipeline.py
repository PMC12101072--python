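"""End-to-end orchestration.

Stage order for a specimen image is fixed: dark-subtract -> computational
filter -> saturated-pixel repair -> normalize -> excitation transform ->
inscribed-square crop -> taper -> FFT -> rotational average -> frequency
range selection (+ per-species harmonization) -> log binning -> slope fit.
Scene images differ only in the crop (centre square) and the normalization
reference (the image's own mean).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from patternspec import acuity as acuity_mod
from patternspec import prep, spectrum
from patternspec.cropping import CropRegion, center_square_crop, largest_inscribed_square
from patternspec.filters import (
    FilterWeights,
    MultispectralStack,
    SensitivityCurve,
    apply_filter_weights,
    fit_computational_filter,
)
from patternspec.io import (
    read_mask_png,
    read_raster_tiff,
    write_mask_png,
    write_raster_tiff,
)
from patternspec.synthetic import (
    PowerLawSpec,
    SyntheticCohortSpec,
    gen_abdomen_mask,
    gen_cohort,
    gen_multispectral_stack,
    gen_powerlaw_image,
    make_filter_bank,
    make_receptor_curve,
)

log = logging.getLogger("patternspec.pipeline")

#: Stage order, asserted by tests and embedded in every report.
STAGE_ORDER = (
    "dark_subtract",
    "computational_filter",
    "repair_saturated",
    "normalize",
    "naka_rushton",
    "crop",
    "cosine_taper",
    "fft",
    "rotational_average",
    "frequency_range",
    "harmonize",
    "bin",
    "fit",
)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the published analysis values."""

    taper_frequency: float = 4.0
    n_bins: int = 9
    min_freq_cpi: int = 5
    max_freq_divisor: int = 10
    harmonization_mode: str = "intent"  # or "literal"
    sensor_width_px: int = acuity_mod.DEFAULT_SENSOR_WIDTH_PX
    fov_mm: float = acuity_mod.DEFAULT_FOV_MM
    distance_mm: float = acuity_mod.DEFAULT_DISTANCE_MM
    inter_receptor_deg: float = acuity_mod.DEFAULT_INTER_RECEPTOR_DEG
    chains: int = 4
    iterations: int = 5000
    warmup: int = 2500
    seed: int = 0

    @property
    def cap_cpmm(self) -> float:
        return acuity_mod.max_analyzed_frequency(self.sensor_width_px, self.fov_mm)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SpecimenSpectrum:
    """Intermediate result: radial spectrum plus crop metadata for one image."""

    unit_id: str
    group: str
    species: str
    sex: str
    region: str
    radial: spectrum.RadialSpectrum
    crop: CropRegion
    f_lo_cpi: int
    f_hi_cpi: int
    repaired_pixels: int = 0


def preprocess_stack(
    stack: MultispectralStack, weights: FilterWeights, scene_mode: bool
) -> prep.ReceptorImage:
    """Dark subtraction, filtering, repair, normalization and excitation."""
    if stack.dark_columns is not None:
        dark = np.array(
            [prep.estimate_dark_noise(stack.dark_columns[i]) for i in range(stack.n_filters)]
        )
    else:
        dark = np.zeros(stack.n_filters)
    # underexposed pixels sit at or below the dark level; overexposed at max
    under = stack.channels <= dark[:, None, None]
    flags = stack.saturated | under
    sub = MultispectralStack(
        channels=np.maximum(stack.channels - dark[:, None, None], 0.0),
        filter_names=stack.filter_names,
        saturated=flags,
        sensor_max=stack.sensor_max,
    )
    receptor, bad = apply_filter_weights(sub, weights)
    repaired, n_repaired = prep.repair_saturated_pixels(receptor, bad)
    if scene_mode:
        ref = float(repaired.mean())
        provenance = "scene_mean"
    else:
        if stack.grey_standard_mask is None:
            raise ValueError("spider image requires a grey-standard region mask")
        ref = float(repaired[stack.grey_standard_mask].mean())
        provenance = "grey_standard"
    normalized = prep.normalize(np.maximum(repaired, 0.0), ref)
    return prep.naka_rushton(normalized, provenance=provenance, repaired_pixels=n_repaired)


def measure_specimen(
    stack: MultispectralStack,
    weights: FilterWeights,
    mask: np.ndarray | None,
    fov_mm: float,
    config: RunConfig,
    unit_id: str = "",
    group: str = "spider",
    species: str = "",
    sex: str = "",
    region: str = "",
) -> SpecimenSpectrum:
    """Run one image up to its radial spectrum (binning and fitting happen
    after species-level harmonization)."""
    scene_mode = group == "scene"
    excitation = preprocess_stack(stack, weights, scene_mode=scene_mode)
    img = excitation.values
    if scene_mode:
        crop = center_square_crop(img)
    else:
        if mask is None:
            raise ValueError("spider image requires an abdomen mask")
        crop = largest_inscribed_square(mask)
    crop = crop.with_calibration(fov_mm, img.shape[1])
    square = crop.extract(img)
    tapered = spectrum.cosine_taper(square, config.taper_frequency)
    amp = spectrum.amplitude_spectrum(tapered)
    radial = spectrum.rotational_average(amp, crop_mm=crop.physical_size_mm)
    f_lo, f_hi = spectrum.select_frequency_range(
        crop.side_px, config.min_freq_cpi, config.max_freq_divisor
    )
    return SpecimenSpectrum(
        unit_id=unit_id,
        group=group,
        species=species,
        sex=sex,
        region=region,
        radial=radial,
        crop=crop,
        f_lo_cpi=f_lo,
        f_hi_cpi=f_hi,
        repaired_pixels=excitation.repaired_pixels,
    )


def fit_harmonized_slopes(
    specs: list[SpecimenSpectrum], config: RunConfig
) -> pd.DataFrame:
    """Harmonize frequency ranges within species, then bin and fit each image."""
    rows = []
    by_species: dict[str, list[SpecimenSpectrum]] = {}
    for s in specs:
        if s.group == "spider":
            by_species.setdefault(s.species, []).append(s)

    ranges: dict[str, tuple[int, int]] = {}
    for sp, members in by_species.items():
        bounds = [
            (m.f_lo_cpi, m.f_hi_cpi, m.crop.physical_size_mm) for m in members
        ]
        _, _, per_member = spectrum.harmonize_species_range(
            bounds, cap_cpmm=config.cap_cpmm, mode=config.harmonization_mode
        )
        for m, (lo, hi) in zip(members, per_member):
            ranges[m.unit_id] = (lo, hi)

    for s in specs:
        f_lo, f_hi = ranges.get(s.unit_id, (s.f_lo_cpi, s.f_hi_cpi))
        binned = spectrum.bin_log_spectrum(s.radial, f_lo, f_hi, n_bins=config.n_bins)
        fit = spectrum.fit_spectral_slope(
            binned, f_lo, f_hi, crop_mm=s.crop.physical_size_mm
        )
        rows.append(
            {
                "unit_id": s.unit_id,
                "group": s.group,
                "species": s.species,
                "sex": s.sex,
                "region": s.region,
                "crop_side_px": s.crop.side_px,
                "crop_mm": s.crop.physical_size_mm,
                "f_lo_cpi": fit.f_lo_cpi,
                "f_hi_cpi": fit.f_hi_cpi,
                "f_lo_cpmm": fit.f_lo_cpmm,
                "f_hi_cpmm": fit.f_hi_cpmm,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "n_bins_used": fit.n_bins,
                "repaired_pixels": s.repaired_pixels,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic study on disk


def simulate_study(
    out_dir: str | Path,
    cohort_spec: SyntheticCohortSpec | None = None,
    image_size: int = 192,
    seed: int = 0,
) -> Path:
    """Write a complete synthetic study (stacks, masks, curves, manifest).

    Each specimen's abdomen pattern is a power-law image whose exponent is
    that specimen's ground-truth slope from the cohort generator, composited
    onto a grey-standard background; scenes are full-frame power-law images.
    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort_spec is None:
        cohort_spec = SyntheticCohortSpec(seed=seed)
    cohort = gen_cohort(cohort_spec)
    cohort.to_csv(out / "cohort_truth.csv", index=False)

    bank = make_filter_bank()
    receptor = make_receptor_curve()
    curves_dir = out / "curves"
    curves_dir.mkdir(exist_ok=True)
    for c in bank:
        c.to_csv(curves_dir / f"{c.name}.csv")
    receptor.to_csv(curves_dir / "receptor_target.csv")
    reflectance = receptor  # scene reflectance matched to the receptor band

    rng = np.random.default_rng(seed)
    manifest_rows = []
    for i, row in cohort.iterrows():
        uid = row["unit_id"]
        sub_seed = int(rng.integers(2**31))
        pattern = gen_powerlaw_image(
            PowerLawSpec(beta=row["slope"], size_px=image_size, seed=sub_seed)
        )
        if row["group"] == "spider":
            mask = gen_abdomen_mask(
                image_size,
                shape="fan" if row["sex"] == "male" else "ellipse",
                seed=sub_seed,
            )
            scene = np.where(mask, pattern, 0.2)  # 20%-reflective grey standard
            grey_mask = ~mask
        else:
            mask = None
            scene = pattern
            grey_mask = None
        stack = gen_multispectral_stack(
            scene, bank, reflectance, dark_offset=250.0, read_noise_sd=2.0,
            seed=sub_seed, grey_standard_mask=grey_mask,
        )
        paths = []
        for k, name in enumerate(stack.filter_names):
            p = out / f"{uid}_{name}.tif"
            write_raster_tiff(p, stack.channels[k])
            paths.append(p.name)
        dark_path = out / f"{uid}_dark.tif"
        write_raster_tiff(dark_path, stack.dark_columns.mean(axis=0))
        mask_name = ""
        if mask is not None:
            mask_name = f"{uid}_mask.png"
            write_mask_png(out / mask_name, mask)
        manifest_rows.append(
            {
                "unit_id": uid,
                "group": row["group"],
                "species": row["species"],
                "sex": row["sex"],
                "region": row["region"],
                # all synthetic captures share the shortest-extension FOV
                "fov_mm": acuity_mod.DEFAULT_FOV_MM,
                "image_paths": ";".join(paths),
                "dark_path": dark_path.name,
                "mask_path": mask_name,
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def run_specimen_batch(
    manifest_path: str | Path, config: RunConfig
) -> tuple[pd.DataFrame, list[str]]:
    """Process every manifest row to a slope fit.

    Per-row failures are collected and reported; remaining rows complete.
    Returns (slope table, error messages).
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    if manifest.empty:
        log.warning("manifest is empty")
        return pd.DataFrame(), []

    bank = [
        SensitivityCurve.from_csv(p)
        for p in sorted((base / "curves").glob("filter_*.csv"))
    ]
    target = SensitivityCurve.from_csv(base / "curves" / "receptor_target.csv")
    weights = fit_computational_filter(bank, target)

    specs: list[SpecimenSpectrum] = []
    errors: list[str] = []
    for _, row in manifest.iterrows():
        try:
            channels = np.stack(
                [read_raster_tiff(base / p) for p in row["image_paths"].split(";")]
            )
            dark2d = read_raster_tiff(base / row["dark_path"]) if row.get("dark_path") else None
            dark = (
                np.repeat(dark2d[None], channels.shape[0], axis=0)
                if dark2d is not None
                else None
            )
            mask = read_mask_png(base / row["mask_path"]) if row["mask_path"] else None
            grey_mask = ~mask if mask is not None else None
            stack = MultispectralStack(
                channels=channels,
                filter_names=[f"ch{k}" for k in range(channels.shape[0])],
                dark_columns=dark,
                saturated=channels >= 65535,
                grey_standard_mask=grey_mask,
            )
            specs.append(
                measure_specimen(
                    stack, weights, mask, float(row["fov_mm"]), config,
                    unit_id=row["unit_id"], group=row["group"],
                    species=row["species"], sex=row["sex"], region=row["region"],
                )
            )
        except Exception as exc:  # noqa: BLE001 - per-row isolation
            errors.append(f"{row['unit_id']}: {exc}")
            log.error("row %s failed: %s", row["unit_id"], exc)
    table = fit_harmonized_slopes(specs, config) if specs else pd.DataFrame()
    return table, errors


def run_full_study(
    manifest_path: str | Path, config: RunConfig, out_dir: str | Path
) -> dict:
    """Specimen + scene batch, hierarchical model, contrasts, acuity, report."""
    from patternspec.stats import contrast, fit_hierarchical_model

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    slopes, errors = run_specimen_batch(manifest_path, config)
    slopes.to_csv(out / "slopes.csv", index=False)

    fit = fit_hierarchical_model(
        slopes.rename(columns={"slope": "slope"}),
        chains=config.chains,
        iterations=config.iterations,
        warmup=config.warmup,
        seed=config.seed,
    )
    summary = fit.summary()
    summary.to_csv(out / "posterior_summary.csv")

    contrasts = {
        "male_vs_female": contrast(fit.stacked("mean_male"), fit.stacked("mean_female")),
    }
    if "mean_scene" in fit.draws:
        contrasts["male_vs_scene"] = contrast(
            fit.stacked("mean_male"), fit.stacked("mean_scene")
        )
        contrasts["female_vs_scene"] = contrast(
            fit.stacked("mean_female"), fit.stacked("mean_scene")
        )

    report = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "stage_order": list(STAGE_ORDER),
        "n_images": int(len(slopes)),
        "errors": errors,
        "acuity": {
            "f_max_cpmm": acuity_mod.max_analyzed_frequency(
                config.sensor_width_px, config.fov_mm
            ),
            "f_s_cpmm": acuity_mod.spatial_resolution_limit(
                config.distance_mm, config.inter_receptor_deg
            ),
        },
        "converged": bool(fit.converged),
        "contrasts": {k: dataclasses.asdict(v) for k, v in contrasts.items()},
        "group_means": {
            k: float(fit.stacked(k).mean())
            for k in ("mean_male", "mean_female", "mean_scene")
            if k in fit.draws
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
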