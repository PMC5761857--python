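"""Published study constants used as simulation inputs and worked-example data.

These are the group-level summary statistics (mean, SD) reported for the
four study groups — healthy controls, chronic NAION eyes, their unaffected
fellow eyes, and moderate-to-severe POAG eyes — together with the published
univariate R-squared between each sectoral PCD and its corresponding RNFL
quadrant thickness, and the published group sizes (eyes). They parameterize
the cohort simulator and the correlation-difference worked examples; they
are inputs, not outputs, of this package.

Units: age in years, axial length in mm, visual-field mean deviation (MD)
in dB (more negative = worse), RNFL thickness in micrometers, PCD in
percent.
"""
from __future__ import annotations

import math

#: (mean, sd) per outcome per group.
GROUP_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    "control": {
        "age_years": (58.4, 10.3),
        "axial_length_mm": (23.0, 1.4),
        "md_db": (-0.6, 1.7),
        "rnfl_global_um": (98.2, 10.3),
        "rnfl_sup_um": (121.3, 20.4),
        "rnfl_nas_um": (74.0, 11.3),
        "rnfl_inf_um": (127.0, 17.4),
        "rnfl_temp_um": (68.8, 12.4),
        "pcd_whole_pct": (42.3, 2.3),
        "pcd_annulus_pct": (43.9, 2.0),
        "pcd_sup_pct": (43.7, 2.2),
        "pcd_nas_pct": (43.3, 2.7),
        "pcd_inf_pct": (43.9, 2.2),
        "pcd_temp_pct": (44.6, 2.2),
    },
    "naion": {
        "age_years": (54.1, 11.0),
        "axial_length_mm": (22.4, 1.5),
        "md_db": (-18.4, 8.6),
        "rnfl_global_um": (59.8, 16.3),
        "rnfl_sup_um": (57.8, 16.1),
        "rnfl_nas_um": (52.7, 23.1),
        "rnfl_inf_um": (69.7, 21.3),
        "rnfl_temp_um": (48.4, 26.5),
        "pcd_whole_pct": (30.1, 6.0),
        "pcd_annulus_pct": (29.7, 6.5),
        "pcd_sup_pct": (26.8, 9.3),
        "pcd_nas_pct": (32.5, 6.8),
        "pcd_inf_pct": (31.2, 7.6),
        "pcd_temp_pct": (28.2, 8.4),
    },
    "fellow": {
        "age_years": (54.1, 11.0),
        "axial_length_mm": (22.2, 1.8),
        "md_db": (-1.0, 2.7),
        "rnfl_global_um": (102.2, 10.5),
        "rnfl_sup_um": (126.4, 19.1),
        "rnfl_nas_um": (80.5, 15.4),
        "rnfl_inf_um": (133.1, 17.3),
        "rnfl_temp_um": (68.1, 13.1),
        "pcd_whole_pct": (41.6, 4.5),
        "pcd_annulus_pct": (42.3, 5.0),
        "pcd_sup_pct": (41.5, 7.0),
        "pcd_nas_pct": (42.9, 4.3),
        "pcd_inf_pct": (42.6, 4.7),
        "pcd_temp_pct": (42.5, 4.9),
    },
    "poag": {
        "age_years": (60.2, 8.0),
        "axial_length_mm": (23.2, 1.3),
        "md_db": (-17.2, 8.6),
        "rnfl_global_um": (64.0, 14.1),
        "rnfl_sup_um": (77.6, 22.4),
        "rnfl_nas_um": (59.0, 15.1),
        "rnfl_inf_um": (66.3, 17.4),
        "rnfl_temp_um": (52.2, 14.6),
        "pcd_whole_pct": (30.2, 5.1),
        "pcd_annulus_pct": (31.3, 5.6),
        "pcd_sup_pct": (29.1, 7.6),
        "pcd_nas_pct": (32.2, 7.9),
        "pcd_inf_pct": (36.1, 6.9),   # the least-affected POAG sector
        "pcd_temp_pct": (28.0, 8.2),
    },
}

#: Female fraction per group (female:male counts 42:35, 15:16, 15:16, 16:26).
FEMALE_FRACTION: dict[str, float] = {
    "control": 42 / 77,
    "naion": 15 / 31,
    "fellow": 15 / 31,
    "poag": 16 / 42,
}

#: Number of analyzed eyes per group.
GROUP_EYES: dict[str, int] = {"control": 77, "naion": 31, "fellow": 31, "poag": 42}

#: Published univariate R-squared between sectoral PCD and the corresponding
#: RNFL quadrant thickness, per pooled analysis group.
SECTOR_R2: dict[str, dict[str, float]] = {
    "poag_control": {"superior": 0.57, "nasal": 0.18, "inferior": 0.46, "temporal": 0.22},
    "naion_fellow": {"superior": 0.45, "nasal": 0.15, "inferior": 0.36, "temporal": 0.16},
}


def sector_correlations(pool: str = "poag_control") -> dict[str, float]:
    """Sector PCD-RNFL Pearson correlations implied by the published R²
    (r = sqrt(R²); all reported slopes are positive)."""
    return {k: math.sqrt(v) for k, v in SECTOR_R2[pool].items()}
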