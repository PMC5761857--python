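"""Perfused capillary density (PCD) percentages and density maps.

PCD of a region is 100 x (perfused-capillary pixels in the region) /
(region pixels), where the region always excludes the inner 1.95-mm
circular area and, by default, the major-vessel pixels (denominator
convention configurable via ``exclude_vessels_from_denominator``). The
whole-image PCD uses the entire frame minus the inner circle; annular and
sectoral PCDs use the corresponding ROI masks.

The color-coded density map evaluates PCD in a 16 x 16-pixel sliding
window with 8-pixel overlaps over the binary image.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import GeometryError
from .geometry import SECTORS, AnnularROI
from .segmentation import PerfusionSegmentation


@dataclass
class PCDResult:
    """Whole-image, whole-annulus and four sectoral PCD percentages for one eye.

    ``numerators``/``denominators`` hold the raw pixel counts per region so
    every percentage can be audited. Percentages are kept at full precision;
    round only at the reporting boundary.
    """

    whole_image_pcd_pct: float
    whole_annulus_pcd_pct: float
    sector_pcd_pct: dict[str, float]
    numerators: dict[str, int]
    denominators: dict[str, int]
    params: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "pcd_whole_pct": self.whole_image_pcd_pct,
            "pcd_annulus_pct": self.whole_annulus_pcd_pct,
        }
        short = {"superior": "sup", "nasal": "nas", "inferior": "inf", "temporal": "temp"}
        for name, s in short.items():
            row[f"pcd_{s}_pct"] = self.sector_pcd_pct[name]
        for region, n in self.numerators.items():
            row[f"n_capillary_px_{region}"] = n
            row[f"n_region_px_{region}"] = self.denominators[region]
        return row


@dataclass
class DensityMap:
    """Grid of per-window PCD percentages (sliding window over the binary)."""

    values: np.ndarray            # percentage per window; NaN where no eligible pixels
    window_px: int
    stride_px: int

    @property
    def origin_offset(self) -> float:
        """Image coordinate of the first window's center."""
        return (self.window_px - 1) / 2.0


def _pcd(capillary: np.ndarray, vessel: np.ndarray, region: np.ndarray,
         exclude_vessels_from_denominator: bool) -> tuple[float, int, int]:
    num = int(np.count_nonzero(capillary & region))
    den_mask = region & ~vessel if exclude_vessels_from_denominator else region
    den = int(np.count_nonzero(den_mask))
    if den == 0:
        raise GeometryError("PCD denominator is empty for the requested region")
    return 100.0 * num / den, num, den


def whole_image_pcd(seg: PerfusionSegmentation, roi: AnnularROI,
                    exclude_vessels_from_denominator: bool = True) -> float:
    """PCD over the entire frame after removing the inner circle (and vessels)."""
    _check_congruent(seg, roi)
    region = ~roi.inner_mask
    pct, _, _ = _pcd(seg.capillary_binary, seg.vessel_mask, region,
                     exclude_vessels_from_denominator)
    return pct


def region_pcd(seg: PerfusionSegmentation, mask: np.ndarray,
               exclude_vessels_from_denominator: bool = True) -> float:
    """PCD restricted to an arbitrary region mask (annulus or one sector)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError("region mask is empty")
    if mask.shape != seg.capillary_binary.shape:
        raise GeometryError(f"mask shape {mask.shape} != segmentation shape {seg.capillary_binary.shape}")
    pct, _, _ = _pcd(seg.capillary_binary, seg.vessel_mask, mask,
                     exclude_vessels_from_denominator)
    return pct


def quantify(seg: PerfusionSegmentation, roi: AnnularROI,
             exclude_vessels_from_denominator: bool = True) -> PCDResult:
    """Compute whole-image, whole-annulus and sectoral PCD for one eye."""
    _check_congruent(seg, roi)
    cap, ves = seg.capillary_binary, seg.vessel_mask
    nums: dict[str, int] = {}
    dens: dict[str, int] = {}
    whole, nums["whole"], dens["whole"] = _pcd(cap, ves, ~roi.inner_mask,
                                               exclude_vessels_from_denominator)
    annulus, nums["annulus"], dens["annulus"] = _pcd(cap, ves, roi.annulus_mask,
                                                     exclude_vessels_from_denominator)
    sectors: dict[str, float] = {}
    for name in SECTORS:
        sectors[name], nums[name], dens[name] = _pcd(cap, ves, roi.sector_masks[name],
                                                     exclude_vessels_from_denominator)
    return PCDResult(
        whole_image_pcd_pct=whole,
        whole_annulus_pcd_pct=annulus,
        sector_pcd_pct=sectors,
        numerators=nums,
        denominators=dens,
        params=dict(seg.params, exclude_vessels_from_denominator=exclude_vessels_from_denominator),
    )


def _check_congruent(seg: PerfusionSegmentation, roi: AnnularROI) -> None:
    if seg.capillary_binary.shape != roi.annulus_mask.shape:
        raise GeometryError(
            f"segmentation grid {seg.capillary_binary.shape} and ROI grid "
            f"{roi.annulus_mask.shape} are not congruent")


def _window_counts(a: np.ndarray, window_px: int, stride_px: int) -> np.ndarray:
    """Sum of ``a`` over each window of the sliding grid, via an integral image."""
    s = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=s[1:, 1:])
    n = (a.shape[0] - window_px) // stride_px + 1
    m = (a.shape[1] - window_px) // stride_px + 1
    r0 = np.arange(n) * stride_px
    c0 = np.arange(m) * stride_px
    r1, c1 = r0 + window_px, c0 + window_px
    return (s[np.ix_(r1, c1)] - s[np.ix_(r0, c1)] - s[np.ix_(r1, c0)] + s[np.ix_(r0, c0)])


def density_map(seg: PerfusionSegmentation, window_px: int = 16, stride_px: int = 8) -> DensityMap:
    """Per-window PCD grid: windows of ``window_px`` tile the image with the
    given stride starting at (0, 0); each cell is 100 x capillary pixels /
    non-vessel pixels in the window (NaN if the window is entirely vessel).
    """
    if not (window_px >= stride_px >= 1):
        raise ValueError(f"need window_px >= stride_px >= 1, got {window_px}, {stride_px}")
    side = seg.capillary_binary.shape[0]
    if window_px > side:
        raise ValueError(f"window_px={window_px} larger than image side {side}")
    cap = _window_counts(seg.capillary_binary.astype(float), window_px, stride_px)
    eligible = _window_counts((~seg.vessel_mask).astype(float), window_px, stride_px)
    eligible = np.rint(eligible)
    cap = np.rint(cap)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(eligible > 0, 100.0 * cap / np.maximum(eligible, 1), np.nan)
    return DensityMap(values=values, window_px=window_px, stride_px=stride_px)


def render_density_map(dm: DensityMap, out_path: str | Path, cmap: str = "turbo",
                       upscale: int = 4) -> Path:
    """Write a color-coded density map PNG with a fixed [0, 100]% scale.

    The colormap is applied on the fixed absolute scale (0% and 100% map to
    the colormap endpoints); NaN cells (all-vessel windows) render black.
    Output bytes are deterministic: no timestamps or run-dependent metadata.
    """
    vals = np.asarray(dm.values, dtype=float)
    cm = colormaps[cmap]
    rgba = cm(np.clip(np.nan_to_num(vals, nan=0.0), 0, 100) / 100.0, bytes=True)
    rgba[np.isnan(vals)] = (0, 0, 0, 255)
    im = Image.fromarray(rgba[..., :3], mode="RGB")
    if upscale > 1:
        im = im.resize((im.width * upscale, im.height * upscale), Image.NEAREST)
    out_path = Path(out_path)
    im.save(out_path, format="PNG")
    return out_path


class PCDQuantifier(BaseEstimator, TransformerMixin):
    """Transformer mapping segmentations to per-eye PCD rows.

    sklearn-style stateless transformer; ``transform`` accepts a list of
    :class:`PerfusionSegmentation` and returns a ``pandas.DataFrame`` with
    one row per eye (ids, group, six PCD percentages, pixel counts).
    Composes with :class:`~pcdquant.segmentation.CapillarySegmenter` in an
    sklearn ``Pipeline``.

    Parameters
    ----------
    inner_mm, outer_mm : float
        Diameters of the concentric ROI circles, in millimeters.
    exclude_vessels_from_denominator : bool, default True
        Whether major-vessel pixels are removed from region denominators.
    """

    def __init__(self, inner_mm: float = 1.95, outer_mm: float = 3.45,
                 exclude_vessels_from_denominator: bool = True):
        self.inner_mm = inner_mm
        self.outer_mm = outer_mm
        self.exclude_vessels_from_denominator = exclude_vessels_from_denominator

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        import pandas as pd

        from .geometry import make_annulus

        single = isinstance(X, PerfusionSegmentation)
        items = [X] if single else list(X)
        rows = []
        for seg in items:
            img = seg.angiogram
            roi = make_annulus(img.center, img.scale_px_per_mm, img.pixels.shape,
                               inner_mm=self.inner_mm, outer_mm=self.outer_mm,
                               laterality=img.laterality)
            res = quantify(seg, roi, self.exclude_vessels_from_denominator)
            row = {
                "subject_id": img.subject_id,
                "eye_id": img.eye_id,
                "laterality": img.laterality,
                "group": img.group,
            }
            row.update(res.as_row())
            rows.append(row)
        return pd.DataFrame(rows)
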