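"""Raster and table IO: 16-bit TIFF rasters, 8-bit PNG masks, CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "write_raster_tiff",
    "read_raster_tiff",
    "write_mask_png",
    "read_mask_png",
    "read_cohort_csv",
    "write_cohort_csv",
]

COHORT_COLUMNS = ["unit_id", "group", "species", "sex", "region", "slope"]


def write_raster_tiff(path: str | Path, raster: np.ndarray) -> None:
    """Write a raster as 16-bit TIFF. Values are clipped to [0, 65535]."""
    arr = np.clip(np.asarray(raster, dtype=float), 0, 65535)
    tifffile.imwrite(str(path), np.round(arr).astype(np.uint16))


def read_raster_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG (0 background / 255 foreground)."""
    arr = (np.asarray(mask).astype(bool) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(str(path)).convert("L")) > 127


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
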