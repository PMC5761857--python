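"""Reading, writing and resizing en-face OCT-A angiograms.

An en-face angiogram is a square grayscale raster covering a known physical
scan field (default 4.5 x 4.5 mm) centered on the optic nerve head (ONH).
Intensities are normalized to [0, 1] on load by dividing by the bit-depth
maximum. All physical geometry downstream is derived from
``scale_px_per_mm = side_px / width_mm``.

Coordinate convention: (row, col), 0-based, row 0 at the top of the image
(superior retina in fundus orientation). The ONH center defaults to the
image center; an explicit ``center_px`` override is accepted.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from skimage.transform import resize as _sk_resize

from .errors import ImageFormatError

LATERALITIES = ("OD", "OS")
GROUPS = ("control", "naion", "fellow", "poag")


@dataclass
class EnFaceAngiogram:
    """Square grayscale angiogram with physical scale and eye metadata.

    Parameters
    ----------
    pixels : ndarray of float
        Square 2-D intensity grid, values in [0, 1].
    width_mm : float
        Physical width of the scan field in millimeters.
    center_px : (float, float), optional
        ONH center as (row, col); defaults to the image center.
    laterality : {"OD", "OS"}
    """

    pixels: np.ndarray
    width_mm: float = 4.5
    center_px: tuple[float, float] | None = None
    laterality: str = "OD"
    subject_id: str = ""
    eye_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ImageFormatError(f"expected a 2-D grayscale grid, got ndim={px.ndim}")
        if px.shape[0] != px.shape[1]:
            raise ImageFormatError(f"expected a square grid, got shape {px.shape}")
        if not np.isfinite(px).all():
            raise ImageFormatError("image contains non-finite intensities")
        if px.size and (px.min() < 0 or px.max() > 1):
            raise ImageFormatError("intensities must lie in [0, 1] after normalization")
        if self.width_mm <= 0:
            raise ImageFormatError("width_mm must be positive")
        if self.laterality not in LATERALITIES:
            raise ImageFormatError(f"laterality must be one of {LATERALITIES}")
        self.pixels = px

    @property
    def side_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def scale_px_per_mm(self) -> float:
        return self.side_px / self.width_mm

    @property
    def center(self) -> tuple[float, float]:
        if self.center_px is not None:
            return tuple(self.center_px)
        c = (self.side_px - 1) / 2.0
        return (c, c)

    def metadata(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "eye_id": self.eye_id,
            "laterality": self.laterality,
            "group": self.group,
            "width_mm": self.width_mm,
            "center_px": list(self.center_px) if self.center_px is not None else None,
        }


def _read_raster(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                if im.mode in ("RGB", "RGBA", "P"):
                    raise ImageFormatError(f"{path}: color images are not supported (mode {im.mode})")
                arr = np.array(im)
    except ImageFormatError:
        raise
    except Exception as exc:  # unreadable / not an image
        raise ImageFormatError(f"{path}: cannot read raster ({exc})") from exc
    return arr


def load_angiogram(path: str | Path, metadata: dict | None = None, *, width_mm: float = 4.5) -> EnFaceAngiogram:
    """Load an 8- or 16-bit grayscale TIFF/PNG as an :class:`EnFaceAngiogram`.

    Intensities are rescaled to [0, 1] by dividing by the bit-depth maximum
    (255 or 65535). A JSON sidecar ``<path>.json`` is read if present;
    an explicit ``metadata`` mapping overrides sidecar values.
    """
    path = Path(path)
    arr = _read_raster(path)
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: expected grayscale, got array of shape {arr.shape}")
    if arr.shape[0] != arr.shape[1]:
        raise ImageFormatError(f"{path}: expected a square image, got {arr.shape}")
    if arr.dtype == np.uint8:
        px = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        px = arr.astype(float) / 65535.0
    else:
        raise ImageFormatError(f"{path}: unsupported bit depth {arr.dtype}; expected uint8 or uint16")

    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    if metadata:
        meta.update(metadata)
    center = meta.get("center_px")
    return EnFaceAngiogram(
        pixels=px,
        width_mm=float(meta.get("width_mm", width_mm)),
        center_px=tuple(center) if center is not None else None,
        laterality=meta.get("laterality", "OD"),
        subject_id=str(meta.get("subject_id", "")),
        eye_id=str(meta.get("eye_id", "")),
        group=str(meta.get("group", "")),
    )


def save_angiogram(img: EnFaceAngiogram, path: str | Path, *, bit_depth: int = 16,
                   sidecar: bool = True) -> Path:
    """Write an angiogram as 8/16-bit grayscale TIFF or PNG plus JSON sidecar.

    Quantization rounds to the nearest representable level, so save/load
    round-trips are exact for images that were themselves loaded at the same
    bit depth.
    """
    path = Path(path)
    if bit_depth == 16:
        arr = np.rint(img.pixels * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.rint(img.pixels * 255.0).astype(np.uint8)
    else:
        raise ImageFormatError(f"unsupported bit depth {bit_depth}")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)
    if sidecar:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(img.metadata(), indent=1))
    return path


def resize_image(img: EnFaceAngiogram, factor: int) -> EnFaceAngiogram:
    """Upsample by an integer factor with bilinear interpolation.

    The physical width is unchanged, so ``scale_px_per_mm`` is multiplied by
    ``factor``. Bilinear interpolation is monotone: output values never
    overshoot the input min/max, and a constant image stays constant.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"resize factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return replace(img, pixels=img.pixels.copy())
    side = img.side_px * factor
    out = _sk_resize(img.pixels, (side, side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    out = np.clip(out, img.pixels.min(), img.pixels.max())
    new_center = None
    if img.center_px is not None:
        new_center = tuple((c + 0.5) * factor - 0.5 for c in img.center_px)
    return replace(img, pixels=out, center_px=new_center)
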