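"""Synthetic angiograms with known ground truth, and synthetic cohorts.

Two generators make every downstream stage testable without patient data:

* :func:`generate_angiogram` draws an en-face angiogram analog on a native
  pixel grid (default 304 x 304 over 4.5 mm): a dark optic-disc analog, a
  configurable number of large radial vessels with a steep-shouldered
  (super-Gaussian) cross-profile whose caliber is the full width at half
  maximum, and a capillary texture of curvilinear thin strokes (1-2 px wide
  at native scale, running in near-parallel bundles with a one-pixel
  inter-capillary gap) filling a target area fraction of the eligible
  region (outside vessels, a one-pixel perivascular free zone, and the
  disc), plus additive Gaussian intensity noise. Ground-truth capillary
  and vessel masks are returned alongside the image.

* :func:`generate_cohort` draws per-eye clinical records (two eyes per
  subject) whose per-group means/SDs, within-subject inter-eye correlation,
  and sector PCD-RNFL Pearson correlations converge to requested targets.
  Correlations are induced by shared latent factors at both the subject and
  the eye level, so the target Pearson r holds marginally while two eyes of
  one subject share a random effect with correlation ``within_subject_rho``.

Intensity calibration of the angiogram generator (background 0.32,
capillary 0.76, vessel peak 0.84, disc 0.10): these place the capillary
edge transition approximately symmetrically around the global threshold
after the 1%/99% contrast stretch, emulating the vendor-normalized
intensity scale that fixed binarization thresholds presuppose. The modest
capillary-to-vessel brightness ratio reflects the saturation of
decorrelation signals at high flow speeds, which makes large vessels only
moderately brighter than capillaries on en-face angiograms.

Acquisition physics (decorrelation statistics, projection artifacts,
motion) are deliberately not simulated.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import reference
from .errors import SimulationError
from .io import EnFaceAngiogram, save_angiogram
from .geometry import SECTORS

# Intensity calibration (see module docstring).
_BG_INTENSITY = 0.32
_CAPILLARY_INTENSITY = 0.76
_VESSEL_PEAK = 0.84
_DISC_INTENSITY = 0.10

_SECTOR_SHORT = {"superior": "sup", "nasal": "nas", "inferior": "inf", "temporal": "temp"}

COHORT_COLUMNS = [
    "subject_id", "eye_id", "laterality", "group", "age_years", "sex",
    "axial_length_mm", "md_db", "rnfl_global_um", "rnfl_sup_um", "rnfl_nas_um",
    "rnfl_inf_um", "rnfl_temp_um", "pcd_whole_pct", "pcd_annulus_pct",
    "pcd_sup_pct", "pcd_nas_pct", "pcd_inf_pct", "pcd_temp_pct",
]


@dataclass(frozen=True)
class AngiogramSimSpec:
    """Parameters of one synthetic angiogram."""

    image_size_px: int = 304
    scan_field_mm: float = 4.5
    capillary_fraction: float = 0.40
    n_major_vessels: int = 8
    vessel_caliber_um: float = 100.0
    disc_radius_mm: float = 0.75
    noise_sd: float = 0.04
    laterality: str = "OD"
    seed: int = 0

    def validate(self) -> None:
        if self.image_size_px < 64:
            raise SimulationError("image_size_px must be >= 64")
        if not 0.0 <= self.capillary_fraction <= 1.0:
            raise SimulationError("capillary_fraction must lie in [0, 1]")
        if self.capillary_fraction > 0.9:
            raise SimulationError(
                "capillary_fraction > 0.9 cannot be synthesized together with the "
                "vessel and disc area without exceeding the frame")
        if self.vessel_caliber_um <= 0:
            raise SimulationError("vessel_caliber_um must be positive")
        if self.n_major_vessels < 0:
            raise SimulationError("n_major_vessels must be >= 0")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.laterality not in ("OD", "OS"):
            raise SimulationError("laterality must be OD or OS")
        if self.scan_field_mm <= 0 or self.disc_radius_mm < 0:
            raise SimulationError("scan_field_mm must be positive and disc_radius_mm >= 0")


@dataclass
class GroundTruth:
    """Per-pixel ground truth accompanying a synthetic angiogram."""

    capillary_mask: np.ndarray
    vessel_mask: np.ndarray
    eligible_mask: np.ndarray
    capillary_fraction: float  # capillary px / eligible px, exactly


def _vessel_centerlines(spec: AngiogramSimSpec, rng: np.random.Generator,
                        center: float, side: int) -> np.ndarray:
    """Rasterize smooth radial vessel centerlines from the disc outward."""
    grid = np.zeros((side, side), dtype=bool)
    if spec.n_major_vessels == 0:
        return grid
    r_max = side * 0.75
    base = rng.uniform(0, 2 * np.pi)
    for i in range(spec.n_major_vessels):
        theta0 = base + 2 * np.pi * i / spec.n_major_vessels + rng.uniform(-0.2, 0.2)
        amp = rng.uniform(0.04, 0.12)
        period = rng.uniform(side * 0.4, side * 0.8)
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(0.0, r_max, 0.5)
        theta = theta0 + amp * np.sin(2 * np.pi * t / period + phase)
        r = np.clip(np.rint(center - t * np.sin(theta)).astype(int), 0, side - 1)
        c = np.clip(np.rint(center + t * np.cos(theta)).astype(int), 0, side - 1)
        inb = (center - t * np.sin(theta) >= 0) & (center - t * np.sin(theta) <= side - 1) & \
              (center + t * np.cos(theta) >= 0) & (center + t * np.cos(theta) <= side - 1)
        grid[r[inb], c[inb]] = True
    return grid


def _draw_capillaries(spec: AngiogramSimSpec, rng: np.random.Generator,
                      eligible: np.ndarray, center: float) -> np.ndarray:
    """Curvilinear thin strokes until the target area fraction is met.

    Strokes follow a near-radial orientation field (radial peripapillary
    capillaries run radially within the RNFL) with jitter and curvature.
    Each stroke is a continuous band of fixed perpendicular width (1.2 or
    2.2 px at the native scale, rasterized by distance to the centerline so
    the width is orientation-independent), and keeps an inter-capillary gap
    of >= 1.5 px from previously drawn strokes so the texture stays
    resolvable. Once spaced packing saturates, any remainder up to the
    target fraction is filled with the gap constraint relaxed.
    """
    side = eligible.shape[0]
    mask = np.zeros_like(eligible)
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise SimulationError("no eligible pixels left for capillary texture")
    target = int(round(spec.capillary_fraction * n_eligible))
    if target == 0:
        return mask
    coords = np.flatnonzero(eligible)
    blocked = np.zeros_like(eligible)      # strokes + their gap halo
    orient = np.full(eligible.shape, np.nan)  # local stroke orientation field
    # wider strokes are needed to pack high fractions
    p_wide = float(np.clip((spec.capillary_fraction - 0.20) / 0.25, 0.3, 1.0))
    gap_px = 1.5
    count = 0

    def paint(pr: np.ndarray, pc: np.ndarray, w: float, phi_mean: float,
              inhibit: bool) -> int:
        """Rasterize one stroke band around a centerline; returns new pixels."""
        nonlocal count
        pad = w / 2 + gap_px + 1
        rlo = max(0, int(np.floor(pr.min() - pad)))
        rhi = min(side, int(np.ceil(pr.max() + pad)) + 1)
        clo = max(0, int(np.floor(pc.min() - pad)))
        chi = min(side, int(np.ceil(pc.max() + pad)) + 1)
        if rhi <= rlo or chi <= clo:
            return 0
        gr = np.arange(rlo, rhi, dtype=float)[:, None]
        gc = np.arange(clo, chi, dtype=float)[None, :]
        # distance from each patch pixel center to the stroke centerline
        dist = np.sqrt(np.min((gr[..., None] - pr) ** 2 + (gc[..., None] - pc) ** 2, axis=-1))
        patch = np.s_[rlo:rhi, clo:chi]
        stroke = (dist <= w / 2) & eligible[patch] & ~mask[patch]
        if inhibit:
            stroke &= ~blocked[patch]
        n_new = int(stroke.sum())
        if n_new:
            mask[patch] |= stroke
            # inhibition: the stroke's 8-neighborhood is off-limits, which
            # guarantees at least a one-pixel gap in every direction
            blocked[patch] |= ndimage.binary_dilation(stroke, structure=np.ones((3, 3), bool))
            sub = orient[patch]
            band = (dist <= w / 2 + gap_px + 2.0) & np.isnan(sub)
            sub[band] = phi_mean
            count += n_new
        return n_new

    def draw_stroke(inhibit: bool, bundle: bool = False) -> int:
        start = coords[rng.integers(len(coords))]
        if inhibit:  # prefer seeding in still-open lanes
            for _ in range(12):
                if not blocked.flat[start]:
                    break
                start = coords[rng.integers(len(coords))]
        r0, c0 = divmod(start, side)
        # adopt the orientation of neighboring strokes (capillaries run in
        # near-parallel bundles), falling back to the radial direction
        local = orient[r0, c0]
        if np.isnan(local):
            phi0 = np.arctan2(r0 - center, c0 - center) + rng.normal(0, 0.25)
        else:
            phi0 = local + rng.normal(0, 0.04)
        if rng.random() < 0.5:
            phi0 += np.pi
        n_steps = int(rng.integers(32, 96))
        phi = phi0 + rng.normal(0, 0.03, n_steps).cumsum()
        pr = r0 + 0.5 * np.sin(phi).cumsum()
        pc = c0 + 0.5 * np.cos(phi).cumsum()
        w = 2.2 if rng.random() < p_wide else 1.2
        phi_mean = float(np.arctan2(np.sin(phi).mean(), np.cos(phi).mean()))
        n_new = paint(pr, pc, w, phi_mean, inhibit)
        if bundle and n_new:
            # fill the local lane lattice with parallel siblings
            nr, nc = np.cos(phi), -np.sin(phi)   # unit normal to the tangent
            pitch = w + 1.35
            for k in (1, -1, 2, -2, 3, -3):
                if count >= target:
                    break
                paint(pr + k * pitch * nr, pc + k * pitch * nc, w, phi_mean, inhibit)
        return n_new

    # phase 1: spaced packing in near-parallel bundles
    stale = 0
    while count < target and stale < 4000:
        before = count
        draw_stroke(inhibit=True, bundle=True)
        stale = stale + 1 if count - before < 6 else 0
    # phase 2: fill any remainder with the gap constraint relaxed
    stale = 0
    while count < target and stale < 6000:
        stale = stale + 1 if draw_stroke(inhibit=False) < 1 else 0
    if abs(count / n_eligible - spec.capillary_fraction) > 0.02:
        raise SimulationError(
            f"could not reach capillary fraction {spec.capillary_fraction:.3f} "
            f"(realized {count / n_eligible:.3f})")
    return mask


def generate_angiogram(spec: AngiogramSimSpec) -> tuple[EnFaceAngiogram, GroundTruth]:
    """Draw one synthetic angiogram plus its ground-truth masks.

    Deterministic given ``spec.seed``. For OS laterality the whole layout is
    the horizontal mirror of the OD layout drawn from the same seed. The
    realized ground-truth capillary fraction (capillary px / eligible px) is
    within +/- 0.02 of ``spec.capillary_fraction``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    side = spec.image_size_px
    scale = side / spec.scan_field_mm  # px per mm
    center = (side - 1) / 2.0

    rows = np.arange(side, dtype=float)[:, None]
    cols = np.arange(side, dtype=float)[None, :]
    dist_center = np.hypot(rows - center, cols - center)
    disc = dist_center <= spec.disc_radius_mm * scale

    centerlines = _vessel_centerlines(spec, rng, center, side)
    fwhm_px = spec.vessel_caliber_um / 1000.0 * scale
    if centerlines.any():
        d = ndimage.distance_transform_edt(~centerlines)
        # steep-shouldered cross-profile (flat lumen, sharp walls); the
        # caliber is the full width at half maximum by construction
        profile = np.exp(-np.log(2.0) * (2.0 * d / fwhm_px) ** 4)
        vessel_gt = d <= fwhm_px / 2.0
        # perivascular capillary-free zone, one native pixel wide
        vessel_buffer = d <= fwhm_px / 2.0 + 1.0
    else:
        profile = np.zeros((side, side))
        vessel_gt = np.zeros((side, side), dtype=bool)
        vessel_buffer = vessel_gt

    eligible = ~vessel_buffer & ~disc
    if spec.capillary_fraction > 0 and eligible.sum() < 0.05 * side * side:
        raise SimulationError("vessel and disc area leave too little room for capillaries")
    cap_mask = _draw_capillaries(spec, rng, eligible, center)

    img = np.full((side, side), _BG_INTENSITY)
    img[disc] = _DISC_INTENSITY
    img = img + (_VESSEL_PEAK - img) * profile
    img[cap_mask] = np.maximum(img[cap_mask], _CAPILLARY_INTENSITY)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)

    eligible_out = eligible
    if spec.laterality == "OS":
        img = np.fliplr(img).copy()
        cap_mask = np.fliplr(cap_mask).copy()
        vessel_gt = np.fliplr(vessel_gt).copy()
        eligible_out = np.fliplr(eligible).copy()

    realized = float(cap_mask.sum() / eligible_out.sum()) if eligible_out.any() else 0.0
    angio = EnFaceAngiogram(pixels=img, width_mm=spec.scan_field_mm,
                            laterality=spec.laterality)
    gt = GroundTruth(capillary_mask=cap_mask, vessel_mask=vessel_gt,
                     eligible_mask=eligible_out, capillary_fraction=realized)
    return angio, gt


def write_angiogram_bundle(img: EnFaceAngiogram, gt: GroundTruth, out_dir: str | Path,
                           stem: str, seed: int | None = None) -> dict[str, Path]:
    """Write image (16-bit TIFF), masks (8-bit PNG) and JSON metadata sidecar."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["image"] = save_angiogram(img, out_dir / f"{stem}.tif", bit_depth=16, sidecar=False)
    for name, mask in (("capillary_mask", gt.capillary_mask), ("vessel_mask", gt.vessel_mask)):
        p = out_dir / f"{stem}_{name}.png"
        Image.fromarray((mask.astype(np.uint8)) * 255).save(p)
        paths[name] = p
    meta = img.metadata()
    meta.update({"seed": seed, "capillary_fraction": gt.capillary_fraction})
    sidecar = out_dir / f"{stem}.tif.json"
    sidecar.write_text(json.dumps(meta, indent=1))
    paths["metadata"] = sidecar
    return paths


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: Outcomes correlated in (PCD, RNFL) pairs per sector.
_SECTOR_PAIRS = {s: (f"pcd_{_SECTOR_SHORT[s]}_pct", f"rnfl_{_SECTOR_SHORT[s]}_um") for s in SECTORS}
#: Remaining eye-level outcomes, mutually independent.
_PLAIN_OUTCOMES = ("axial_length_mm", "md_db", "rnfl_global_um",
                   "pcd_whole_pct", "pcd_annulus_pct")


@dataclass(frozen=True)
class CohortSimSpec:
    """Parameters of one synthetic cohort.

    ``group_params`` maps group -> outcome -> (mean, sd); defaults to the
    published study summaries. ``sector_correlations`` maps sector ->
    target Pearson r between the sector PCD and its corresponding RNFL
    thickness (defaults to the square roots of the published pooled R²).
    ``within_subject_rho`` is the correlation of the two eyes' residuals of
    one subject, applied to every eye-level outcome.
    """

    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"control": 39, "naion": 16, "fellow": 16, "poag": 21})
    group_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in reference.GROUP_SUMMARIES.items()})
    sector_correlations: dict[str, float] = field(
        default_factory=lambda: reference.sector_correlations("poag_control"))
    within_subject_rho: float = 0.4
    female_fraction: dict[str, float] = field(
        default_factory=lambda: dict(reference.FEMALE_FRACTION))
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_subjects.items():
            if n < 2:
                raise SimulationError(f"n_subjects must be >= 2 per group (group {g!r}: {n})")
            if g not in self.group_params:
                raise SimulationError(f"no group_params for group {g!r}")
        for g, params in self.group_params.items():
            for outcome, (_, sd) in params.items():
                if sd <= 0:
                    raise SimulationError(f"SD must be > 0 ({g}/{outcome})")
        for s, r in self.sector_correlations.items():
            if abs(r) > 1:
                raise SimulationError(f"|r| must be <= 1 (sector {s}: {r})")
        if not 0.0 <= self.within_subject_rho < 1.0:
            raise SimulationError("within_subject_rho must lie in [0, 1)")


def _bivariate_pair(rng: np.random.Generator, n: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """n draws of a standard bivariate normal with correlation r."""
    a = rng.standard_normal(n)
    b = r * a + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    return a, b


def generate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table, two eyes per subject.

    For every eye-level outcome the standardized residual is
    ``sqrt(rho) * u_subject + sqrt(1 - rho) * e_eye`` so two eyes of one
    subject correlate at ``within_subject_rho``. For each sector, the PCD
    and RNFL latents are drawn jointly with correlation ``r`` at both the
    subject and the eye level, which makes the marginal Pearson correlation
    between the two observed outcomes equal ``r``. Values are clipped to
    physical ranges (PCD to [0, 100], RNFL and axial length positive, age
    >= 18). Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rho = spec.within_subject_rho
    sr, se = np.sqrt(rho), np.sqrt(1.0 - rho)
    frames = []
    for group in sorted(spec.n_subjects):
        params = spec.group_params[group]
        n_subj = spec.n_subjects[group]
        n_eyes = 2 * n_subj

        def residual(r_pair: float | None = None):
            """Standardized eye-level residuals, one column per eye."""
            if r_pair is None:
                u = np.repeat(rng.standard_normal(n_subj), 2)
                e = rng.standard_normal(n_eyes)
                return sr * u + se * e
            up, ur = _bivariate_pair(rng, n_subj, r_pair)
            ep, er = _bivariate_pair(rng, n_eyes, r_pair)
            return sr * np.repeat(up, 2) + se * ep, sr * np.repeat(ur, 2) + se * er

        data: dict[str, np.ndarray] = {}
        mu_age, sd_age = params["age_years"]
        data["age_years"] = np.maximum(np.repeat(mu_age + sd_age * rng.standard_normal(n_subj), 2), 18.0)
        female = rng.random(n_subj) < spec.female_fraction.get(group, 0.5)
        data["sex"] = np.repeat(np.where(female, "F", "M"), 2)

        for outcome in _PLAIN_OUTCOMES:
            mu, sd = params[outcome]
            data[outcome] = mu + sd * residual()
        for sector, (pcd_col, rnfl_col) in _SECTOR_PAIRS.items():
            zp, zr = residual(spec.sector_correlations[sector])
            mu_p, sd_p = params[pcd_col]
            mu_r, sd_r = params[rnfl_col]
            data[pcd_col] = mu_p + sd_p * zp
            data[rnfl_col] = mu_r + sd_r * zr

        for col in data:
            if col.startswith("pcd_"):
                data[col] = np.clip(data[col], 0.0, 100.0)
            elif col.startswith("rnfl_"):
                data[col] = np.maximum(data[col], 1.0)
            elif col == "axial_length_mm":
                data[col] = np.maximum(data[col], 15.0)

        subj_ids = [f"{group}-{i:05d}" for i in range(n_subj)]
        lat = np.tile(["OD", "OS"], n_subj)
        df = pd.DataFrame({
            "subject_id": np.repeat(subj_ids, 2),
            "laterality": lat,
            "group": group,
            **data,
        })
        df["eye_id"] = df["subject_id"] + "-" + df["laterality"]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[COHORT_COLUMNS]


def write_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort table as CSV with the documented column order."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path
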