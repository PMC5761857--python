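# CSV schemas

## Cohort table (input to `analyze`, output of `simulate-cohort`)

One row per eye; at most two eyes per subject.

| column | type | meaning |
|---|---|---|
| `subject_id` | str | subject identifier (shared by both eyes) |
| `eye_id` | str | unique eye identifier |
| `laterality` | `OD`/`OS` | right/left eye |
| `group` | `control`/`naion`/`fellow`/`poag` | study group |
| `age_years` | float | age in years |
| `sex` | `F`/`M` | encoded as female indicator in models |
| `axial_length_mm` | float | axial length, mm |
| `md_db` | float | visual-field mean deviation, dB (more negative = worse) |
| `rnfl_global_um` | float | average circumpapillary RNFL thickness, µm |
| `rnfl_sup_um`, `rnfl_nas_um`, `rnfl_inf_um`, `rnfl_temp_um` | float | quadrant RNFL thickness, µm |
| `pcd_whole_pct` | float | whole-image PCD, % |
| `pcd_annulus_pct` | float | whole-annulus PCD, % |
| `pcd_sup_pct`, `pcd_nas_pct`, `pcd_inf_pct`, `pcd_temp_pct` | float | sector PCD, % |

## Quantification results (`quantify` → `pcd_results.csv`)

One row per eye: `config_hash`, `subject_id`, `eye_id`, `laterality`,
`group`, the six PCD percentages above, and raw pixel counts
`n_capillary_px_<region>` / `n_region_px_<region>` for region ∈ whole,
annulus, superior, nasal, inferior, temporal, plus `source` (input file).

## Analysis outputs (`analyze`)

* `group_comparisons.csv` — one row per outcome × group pair: `estimate`
  (adjusted mean difference, group_a − group_b), `se`, `z`, 95% CI bounds,
  `p_raw`, `p_bonf`, `model` (`mixed` or `ols`).
* `sector_contrasts.csv` — one row per group × sector pair: mean within-eye
  difference, SD, n, t, `p_raw`, `p_bonf` (×6).
* `regressions.csv` — univariable fits per analysis pool: slope with CI,
  `r`, `r2`, `p`, `n`.
* `correlation_differences.csv` — per pool and sector pair: the two
  PCD–RNFL correlations, their difference, Dunn–Clark `z`, `p`, `n` (eyes).

Every output carries the `config_hash` of the run configuration.
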