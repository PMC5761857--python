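"""Annular region of interest and anatomical sector masks.

The region of interest is the annulus between two concentric circles of
1.95 mm (inner) and 3.45 mm (outer) diameter centered on the ONH — a ring
0.75 mm wide whose outer diameter parallels the standard circumpapillary
RNFL scan circle. The annulus is split into four 90-degree quadrants
bounded by the 45-degree diagonals (superior wedge centered at 12 o'clock),
matching the quadrant convention of circumpapillary RNFL reports.

Anatomical mapping of the horizontal quadrants depends on eye laterality:
for a right eye (OD) displayed in fundus orientation the temporal retina is
the left image half; for a left eye (OS) it is mirrored. Distances and
angles are measured from pixel centers, so pixel counts are unbiased area
estimates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .io import LATERALITIES

SECTORS = ("superior", "nasal", "inferior", "temporal")


@dataclass
class AnnularROI:
    """Concentric-circle geometry plus the four sector masks."""

    center_px: tuple[float, float]
    scale_px_per_mm: float
    inner_diameter_mm: float
    outer_diameter_mm: float
    laterality: str
    inner_mask: np.ndarray
    annulus_mask: np.ndarray
    sector_masks: dict[str, np.ndarray]

    @property
    def annulus_width_mm(self) -> float:
        return (self.outer_diameter_mm - self.inner_diameter_mm) / 2.0


def _quadrant_fields(shape: tuple[int, int], center_px: tuple[float, float]):
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    up = center_px[0] - rows          # positive above the center (superior)
    right = cols - center_px[1]       # positive to the image right
    return up, right


def make_annulus(center_px: tuple[float, float], scale_px_per_mm: float,
                 shape: tuple[int, int], inner_mm: float = 1.95,
                 outer_mm: float = 3.45, laterality: str = "OD") -> AnnularROI:
    """Build the annular ROI and its four sector masks on a pixel grid.

    A pixel belongs to the annulus iff its center lies at radial distance
    ``d`` with ``inner_radius <= d < outer_radius`` (half-open, so the inner
    disk and the annulus never overlap). The outer circle must fit entirely
    within the image.
    """
    if not (outer_mm > inner_mm > 0):
        raise GeometryError(f"need outer_mm > inner_mm > 0, got inner={inner_mm}, outer={outer_mm}")
    if scale_px_per_mm <= 0:
        raise GeometryError("scale_px_per_mm must be positive")
    if laterality not in LATERALITIES:
        raise GeometryError(f"unknown laterality {laterality!r}; expected one of {LATERALITIES}")
    r_in = inner_mm / 2.0 * scale_px_per_mm
    r_out = outer_mm / 2.0 * scale_px_per_mm
    cr, cc = center_px
    for c, side in ((cr, shape[0]), (cc, shape[1])):
        if c - r_out < -0.5 or c + r_out > side - 0.5:
            raise GeometryError(
                f"outer circle (radius {r_out:.1f} px at center {center_px}) exceeds image bounds {shape}")

    up, right = _quadrant_fields(shape, center_px)
    dist = np.hypot(up, right)
    inner_mask = dist < r_in
    annulus = (dist >= r_in) & (dist < r_out)

    # Quadrants bounded by the 45-degree diagonals. Ties (|up| == |right|)
    # go to the vertical sectors, which keeps labels invariant under a
    # left-right mirror combined with an OD<->OS swap.
    sup = (up > 0) & (np.abs(up) >= np.abs(right))
    inf = (up < 0) & (np.abs(up) >= np.abs(right))
    left = ~sup & ~inf & (right < 0)
    rightm = ~sup & ~inf & (right > 0)
    if laterality == "OD":
        temporal, nasal = left, rightm
    else:
        temporal, nasal = rightm, left
    sector_masks = {
        "superior": sup & annulus,
        "nasal": nasal & annulus,
        "inferior": inf & annulus,
        "temporal": temporal & annulus,
    }
    return AnnularROI(
        center_px=tuple(center_px),
        scale_px_per_mm=scale_px_per_mm,
        inner_diameter_mm=inner_mm,
        outer_diameter_mm=outer_mm,
        laterality=laterality,
        inner_mask=inner_mask,
        annulus_mask=annulus,
        sector_masks=sector_masks,
    )


def sector_masks(roi: AnnularROI) -> dict[str, np.ndarray]:
    """Return the four anatomical sector masks of an annular ROI."""
    return roi.sector_masks


def annulus_for_angiogram(img, inner_mm: float = 1.95, outer_mm: float = 3.45) -> AnnularROI:
    """Convenience: build the ROI from an angiogram's center, scale and laterality."""
    return make_annulus(img.center, img.scale_px_per_mm, img.pixels.shape,
                        inner_mm=inner_mm, outer_mm=outer_mm, laterality=img.laterality)
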