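"""Analysis-square extraction.

Spider images are cropped to the largest axis-aligned square inscribed in
the abdomen mask; scene images are cropped to the centre square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["CropRegion", "largest_inscribed_square", "center_square_crop"]


@dataclass(frozen=True)
class CropRegion:
    """Axis-aligned square region, 0-based half-open coordinates.

    ``physical_size_mm`` is populated when a field-of-view calibration is
    supplied: side_px * (fov_mm / source_width_px).
    """

    row0: int
    col0: int
    side_px: int
    physical_size_mm: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.side_px < 1:
            raise ValueError("side_px must be >= 1")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.side_px),
            slice(self.col0, self.col0 + self.side_px),
        )

    def extract(self, image: np.ndarray) -> np.ndarray:
        return image[self.slices]

    def with_calibration(self, fov_mm: float, source_width_px: int) -> "CropRegion":
        """Return a copy with physical_size_mm set from the FOV calibration."""
        if fov_mm <= 0 or source_width_px <= 0:
            raise ValueError("fov_mm and source_width_px must be positive")
        mm = self.side_px * (fov_mm / source_width_px)
        return CropRegion(self.row0, self.col0, self.side_px, mm)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    warnings.warn(
        f"mask has {n} connected components; using the largest", stacklevel=3
    )
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def largest_inscribed_square(mask: np.ndarray) -> CropRegion:
    """Largest axis-aligned all-foreground square inside a binary mask.

    Uses the maximal-square dynamic programme: dp[i, j] is the side of the
    largest square whose bottom-right corner is (i, j).  Among maximal
    squares, the one whose centre lies nearest the foreground centroid wins;
    remaining ties go to the smallest row0, then smallest col0.

    Parameters
    ----------
    mask : bool or 0/1 array.  Multi-component masks are reduced to their
        largest 4-connected component (with a warning).

    Raises
    ------
    ValueError if the mask has no foreground pixel.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("mask has no foreground pixel")
    mask = _largest_component(mask)

    h, w = mask.shape
    dp = np.zeros((h, w), dtype=np.int32)
    dp[0, :] = mask[0, :]
    dp[:, 0] = mask[:, 0]
    m = mask.view(np.uint8)
    for i in range(1, h):
        row = dp[i]
        prev = dp[i - 1]
        mi = m[i]
        # dp[i,j] = min(dp[i-1,j], dp[i,j-1], dp[i-1,j-1]) + 1 where mask
        for j in range(1, w):
            if mi[j]:
                row[j] = min(prev[j], row[j - 1], prev[j - 1]) + 1

    side = int(dp.max())
    rows, cols = np.nonzero(dp == side)
    r0 = rows - side + 1
    c0 = cols - side + 1

    centroid = ndimage.center_of_mass(mask)
    # square centres (row, col) of each candidate
    cr = r0 + (side - 1) / 2.0
    cc = c0 + (side - 1) / 2.0
    d2 = (cr - centroid[0]) ** 2 + (cc - centroid[1]) ** 2
    order = np.lexsort((c0, r0, np.round(d2, 9)))
    best = order[0]
    return CropRegion(int(r0[best]), int(c0[best]), side)


def center_square_crop(image_or_shape) -> CropRegion:
    """Centre square of a (possibly rectangular) raster.

    Side = min(height, width); the offset along the long axis is
    floor((long - side) / 2).  Accepts an array or an (h, w) shape tuple.
    """
    if isinstance(image_or_shape, tuple):
        h, w = image_or_shape
    else:
        arr = np.asarray(image_or_shape)
        if arr.ndim != 2:
            raise ValueError("image must be 2-D")
        h, w = arr.shape
    side = min(h, w)
    row0 = (h - side) // 2
    col0 = (w - side) // 2
    return CropRegion(int(row0), int(col0), int(side))
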