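"""Binarization of en-face angiograms into perfused-capillary maps.

The quantification algorithm converts a grayscale angiogram into a binary
perfused-capillary map in four steps, in this order:

1. contrast stretch using the lowest and highest 1% of pixel intensities as
   the lower and upper limits;
2. global thresholding: pixels with stretched intensity strictly > 0.55
   become white;
3. removal of the large (major) blood vessels from the binary image, based
   on local vessel caliber measured with a distance transform along the
   skeleton;
4. local adaptive thresholding with a 15 x 15-pixel sampling window to
   account for local differences in brightness.

The adaptive threshold operates on the contrast-stretched grayscale (vessel
pixels excluded from the local-mean windows) and is combined with the
global binary by AND, so the final capillary map is
``global AND adaptive AND NOT vessel``. Both thresholds use a strict ">";
ties go to black.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, skeletonize
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateImageError, GeometryError
from .io import EnFaceAngiogram, resize_image

# Numeric guard for the strict ">" comparisons: differences below this are
# treated as ties (relevant only for exactly-flat neighborhoods, where
# floating-point filter round-off must not flip the convention).
_TIE_EPS = 1e-9


@dataclass
class PerfusionSegmentation:
    """Binary capillary map plus major-vessel mask for one angiogram.

    ``capillary_binary`` and ``vessel_mask`` are disjoint by construction.
    All intermediates (stretched grayscale, global binary, adaptive binary)
    are retained for inspection.
    """

    capillary_binary: np.ndarray
    vessel_mask: np.ndarray
    global_binary: np.ndarray
    adaptive_binary: np.ndarray
    stretched: np.ndarray
    angiogram: EnFaceAngiogram
    params: dict = field(default_factory=dict)

    @property
    def scale_px_per_mm(self) -> float:
        return self.angiogram.scale_px_per_mm


def contrast_stretch(pixels: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Linearly map the [low_pct, high_pct] intensity percentiles to [0, 1].

    Percentiles use linear interpolation between order statistics. Output
    is clipped to [0, 1]. A near-constant image (the two percentiles
    coincide) is a degenerate input and raises.
    """
    pixels = np.asarray(pixels, dtype=float)
    lo, hi = np.percentile(pixels, [low_pct, high_pct])
    if hi - lo <= _TIE_EPS:
        raise DegenerateImageError(
            f"percentiles {low_pct}% and {high_pct}% coincide ({lo:.4g}); image is near-constant")
    return np.clip((pixels - lo) / (hi - lo), 0.0, 1.0)


def global_threshold(pixels: np.ndarray, t: float = 0.55) -> np.ndarray:
    """Binary map of pixels with intensity strictly greater than ``t``."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    return np.asarray(pixels, dtype=float) > t


def adaptive_threshold(pixels: np.ndarray, window_px: int = 15,
                       exclude_mask: np.ndarray | None = None) -> np.ndarray:
    """Binary map of pixels strictly brighter than their local-window mean.

    The mean is taken over a ``window_px`` x ``window_px`` neighborhood with
    mirror padding at the borders. Pixels under ``exclude_mask`` (major
    vessels) contribute neither to the means nor to the output.
    """
    pixels = np.asarray(pixels, dtype=float)
    if window_px % 2 == 0 or window_px < 3:
        raise ValueError(f"window_px must be odd and >= 3, got {window_px}")
    if window_px > min(pixels.shape):
        raise ValueError(f"window_px={window_px} larger than image {pixels.shape}")
    if exclude_mask is None:
        local_mean = ndimage.uniform_filter(pixels, size=window_px, mode="mirror")
    else:
        w = (~np.asarray(exclude_mask, dtype=bool)).astype(float)
        num = ndimage.uniform_filter(pixels * w, size=window_px, mode="mirror")
        den = ndimage.uniform_filter(w, size=window_px, mode="mirror")
        with np.errstate(invalid="ignore", divide="ignore"):
            local_mean = np.where(den > 0, num / np.maximum(den, 1e-12), np.inf)
    out = pixels > local_mean + _TIE_EPS
    if exclude_mask is not None:
        out &= ~np.asarray(exclude_mask, dtype=bool)
    return out


def detect_major_vessels(binary: np.ndarray, scale_px_per_mm: float,
                         caliber_cutoff_um: float = 40.0,
                         dilation_px: int = 2,
                         min_extent_mm: float = 1.0) -> np.ndarray:
    """Mask the large radial vessels in a binary perfusion map.

    Local caliber is measured as twice the Euclidean distance-transform
    value sampled along the skeleton of the binary image, converted to
    micrometers via the pixel scale. Skeleton pixels whose caliber exceeds
    ``caliber_cutoff_um`` form vessel cores. Major radial vessels traverse
    the peripapillary field, so core components whose spatial extent is
    below ``min_extent_mm`` (compact blobs at capillary crossings, not
    elongated vessels) are discarded. The vessel body is reconstructed as
    the union of disks of radius ``dt(p)`` around each core pixel ``p``,
    then dilated by ``dilation_px`` to absorb the dim vessel margin.
    Capillary-scale structures are untouched.
    """
    if caliber_cutoff_um <= 0:
        raise ValueError("caliber_cutoff_um must be positive")
    if not np.isfinite(scale_px_per_mm) or scale_px_per_mm <= 0:
        raise GeometryError("pixel scale metadata missing; cannot convert caliber to micrometers")
    binary = np.asarray(binary, dtype=bool)
    out = np.zeros_like(binary)
    if not binary.any():
        return out
    um_per_px = 1000.0 / scale_px_per_mm
    dt = ndimage.distance_transform_edt(binary)
    skel = skeletonize(binary)
    caliber_um = 2.0 * dt * um_per_px
    core = skel & (caliber_um > caliber_cutoff_um)
    if not core.any():
        return out

    min_extent_px = min_extent_mm * scale_px_per_mm
    labels, n = ndimage.label(core, structure=np.ones((3, 3), dtype=int))
    if n:
        keep = []
        for i, sl in enumerate(ndimage.find_objects(labels), start=1):
            if sl is None:
                continue
            extent = max(sl[0].stop - sl[0].start, sl[1].stop - sl[1].start)
            if extent >= min_extent_px:
                keep.append(i)
        core = np.isin(labels, keep) if keep else np.zeros_like(core)
    if not core.any():
        return out

    # Disk-union reconstruction: a pixel is vessel if it lies within the
    # inscribed-disk radius of its nearest core pixel.
    dist_to_core, (ir, ic) = ndimage.distance_transform_edt(~core, return_indices=True)
    out = dist_to_core <= dt[ir, ic]
    if dilation_px > 0:
        out = ndimage.binary_dilation(out, structure=disk(int(dilation_px)).astype(bool))
    return out


def segment(img: EnFaceAngiogram, *, stretch_low_pct: float = 1.0,
            stretch_high_pct: float = 99.0, global_thresh: float = 0.55,
            adaptive_window_px: int = 15, vessel_caliber_cutoff_um: float = 40.0,
            vessel_dilation_px: int = 2, vessel_min_extent_mm: float = 1.0) -> PerfusionSegmentation:
    """Run the full binarization: stretch, global threshold, vessel removal,
    adaptive threshold, and combination into the capillary map.

    A constant (e.g. blank) image yields an empty segmentation rather than
    the degenerate-input error of :func:`contrast_stretch`, since "no signal"
    is a meaningful end-to-end outcome.
    """
    params = {
        "stretch_low_pct": stretch_low_pct,
        "stretch_high_pct": stretch_high_pct,
        "global_threshold": global_thresh,
        "adaptive_window_px": adaptive_window_px,
        "vessel_caliber_cutoff_um": vessel_caliber_cutoff_um,
        "vessel_dilation_px": vessel_dilation_px,
        "vessel_min_extent_mm": vessel_min_extent_mm,
    }
    px = img.pixels
    try:
        stretched = contrast_stretch(px, stretch_low_pct, stretch_high_pct)
    except DegenerateImageError:
        empty = np.zeros(px.shape, dtype=bool)
        return PerfusionSegmentation(empty, empty.copy(), empty.copy(), empty.copy(),
                                     np.zeros_like(px), img, params)
    gbin = global_threshold(stretched, global_thresh)
    vessels = detect_major_vessels(gbin, img.scale_px_per_mm,
                                   caliber_cutoff_um=vessel_caliber_cutoff_um,
                                   dilation_px=vessel_dilation_px,
                                   min_extent_mm=vessel_min_extent_mm)
    abin = adaptive_threshold(stretched, adaptive_window_px, exclude_mask=vessels)
    capillary = gbin & abin & ~vessels
    return PerfusionSegmentation(capillary, vessels, gbin, abin, stretched, img, params)


class CapillarySegmenter(BaseEstimator, TransformerMixin):
    """Transformer mapping angiograms to perfused-capillary segmentations.

    A stateless sklearn-style transformer: ``fit`` validates and returns
    ``self``; ``transform`` upsamples each angiogram by ``resize_factor``
    (bilinear) and applies the four-step binarization. Composes with
    :class:`~pcdquant.metrics.PCDQuantifier` in an sklearn ``Pipeline``.

    Parameters
    ----------
    resize_factor : int, default 6
        Integer upsampling factor applied before thresholding.
    global_threshold : float, default 0.55
        Strict global threshold on the contrast-stretched intensities.
    adaptive_window_px : int, default 15
        Side of the local-mean sampling window (odd), on the resized grid.
    vessel_caliber_cutoff_um : float, default 40.0
        Structures with skeleton caliber above this are removed as major
        vessels.
    vessel_dilation_px : int, default 2
        Dilation of the detected vessel mask, on the resized grid.
    """

    def __init__(self, resize_factor: int = 6, global_threshold: float = 0.55,
                 adaptive_window_px: int = 15, vessel_caliber_cutoff_um: float = 40.0,
                 vessel_dilation_px: int = 2, vessel_min_extent_mm: float = 1.0,
                 stretch_low_pct: float = 1.0, stretch_high_pct: float = 99.0):
        self.resize_factor = resize_factor
        self.global_threshold = global_threshold
        self.adaptive_window_px = adaptive_window_px
        self.vessel_caliber_cutoff_um = vessel_caliber_cutoff_um
        self.vessel_dilation_px = vessel_dilation_px
        self.vessel_min_extent_mm = vessel_min_extent_mm
        self.stretch_low_pct = stretch_low_pct
        self.stretch_high_pct = stretch_high_pct

    def fit(self, X, y=None):
        self._validate_params_()
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> list[PerfusionSegmentation]:
        self._validate_params_()
        single = isinstance(X, EnFaceAngiogram)
        items = [X] if single else list(X)
        out = []
        for img in items:
            if not isinstance(img, EnFaceAngiogram):
                raise TypeError(f"expected EnFaceAngiogram inputs, got {type(img).__name__}")
            resized = resize_image(img, self.resize_factor)
            out.append(segment(
                resized,
                stretch_low_pct=self.stretch_low_pct,
                stretch_high_pct=self.stretch_high_pct,
                global_thresh=self.global_threshold,
                adaptive_window_px=self.adaptive_window_px,
                vessel_caliber_cutoff_um=self.vessel_caliber_cutoff_um,
                vessel_dilation_px=self.vessel_dilation_px,
                vessel_min_extent_mm=self.vessel_min_extent_mm,
            ))
        return out[0] if single else out

    def _validate_params_(self) -> None:
        if int(self.resize_factor) != self.resize_factor or self.resize_factor < 1:
            raise ValueError("resize_factor must be a positive integer")
        if not 0.0 <= self.global_threshold <= 1.0:
            raise ValueError("global_threshold must lie in [0, 1]")
        if self.adaptive_window_px % 2 == 0 or self.adaptive_window_px < 3:
            raise ValueError("adaptive_window_px must be odd and >= 3")
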