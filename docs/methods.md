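# Methods

## Quantification model

The pipeline treats an en-face OCT-A scan as a square intensity raster with
a known physical width (default 4.5 mm) centered on the optic nerve head.
All geometry is derived from `scale_px_per_mm = side_px / width_mm`; the
native grid is configurable and defaults to 304 × 304 (a common en-face
export size), giving 67.6 px/mm natively and 405.3 px/mm after the ×6
upsampling at which all thresholding operates.

Binarization is deliberately simple and fully parameterized:

1. **Resize ×6**, bilinear. Bilinear interpolation is monotone (no
   overshoot), so binary decisions downstream are not affected by ringing.
2. **Contrast stretch** maps the 1st/99th intensity percentiles (linear
   interpolation between order statistics) to 0/1 with clipping. This makes
   the fixed thresholds below meaningful across acquisitions with different
   gain. A near-constant image has no stretch and is a degenerate input;
   the full pipeline maps it to an empty segmentation instead ("no signal"
   is a valid end-to-end outcome).
3. **Global threshold**: stretched intensity strictly > 0.55. Ties go to
   black at both thresholds; numerically, a difference below 1e-9 counts as
   a tie so float round-off in box filters cannot flip the convention.
4. **Major-vessel removal.** Local caliber is measured as twice the
   Euclidean distance-transform value sampled along the skeleton of the
   binary map, converted to µm. Skeleton pixels with caliber above the
   cutoff (default 40 µm — about twice the width of a capillary and well
   below arteriolar caliber) are vessel-core candidates; candidate
   components whose spatial extent falls below 1 mm are rejected, because
   major radial vessels traverse the peripapillary field while
   capillary-crossing artifacts are local blobs. The vessel body is the
   union of inscribed disks around core pixels, dilated by 2 px to absorb
   the dim margin. Cutoff, dilation and minimum extent are configurable.
5. **Adaptive threshold**: stretched intensity strictly greater than the
   mean of its 15 × 15-px neighborhood (mirror padding at borders; vessel
   pixels excluded from the means and from the output). The result is
   combined with the global binary by AND. Applying the local threshold to
   the stretched grayscale rather than to the binary map is the only
   reading under which the step can correct local brightness differences;
   the AND preserves the stage order (global first, vessels removed, then
   local refinement).

**Density metrics.** PCD of a region is 100 · capillary px / region px.
Major-vessel pixels are excluded from the denominator of *every* region by
default (`exclude_vessels_from_denominator=True`): the whole-image
definition requires it explicitly and applying the same convention to the
annulus and sectors keeps the regions comparable; the flag preserves the
alternative reading. The whole-image region is the full frame minus the
inner 1.95-mm circle (pixels outside the 3.45-mm circle are included). The
annulus uses half-open radial bounds `inner ≤ d < outer` measured from pixel
centers, so inner disk, annulus and exterior partition the frame exactly.
Sectors are the four quadrants bounded by the 45° diagonals, superior wedge
centered at 12 o'clock, matching the quadrant convention of circumpapillary
RNFL reports; ties on the diagonals go to the vertical sectors, which makes
sector labels invariant under a horizontal mirror combined with an OD↔OS
swap. For a right eye displayed in fundus orientation the temporal retina is
the left image half; `--flip-nasal-temporal` covers other export
orientations. Reported percentages are kept at full precision internally
and rounded only at the reporting boundary (tables print one decimal).

The density map slides a 16 × 16-px window with stride 8 from the image
origin; each cell is the PCD of its window (NaN if the window is entirely
vessel). Rendering uses a fixed absolute [0, 100]% color scale (`turbo`),
so maps of different eyes are directly comparable, and writes deterministic
bytes (no timestamps).

## Cohort statistics

`compare_groups` fits outcome ~ group + age + sex + axial length with a
subject-level random intercept (REML) to absorb the correlation between two
eyes of one subject, then tests all pairwise group contrasts with Wald z
statistics, Bonferroni-corrected over the number of pairs (6 for four
groups; configurable). Inference is large-sample (z); with the group sizes
this package targets (tens of eyes per group) the difference from
denominator-degree-of-freedom corrections is negligible. When every subject
contributes exactly one eye the random intercept is unidentifiable and the
fit degenerates, exactly, to OLS with the same fixed effects. Sex enters as
a binary indicator; no interactions. Missing data are handled
complete-case per analysis, with dropped-row counts surfaced as warnings.

`sector_contrasts` forms the within-eye difference for each of the six
sector pairs and applies a paired t-test, Bonferroni-corrected for six
comparisons; a pair with identically zero differences gets p = 1.

`univariate_fit` is ordinary least squares of one outcome on one predictor,
reporting the slope with 95% CI, R², and the Pearson correlation
reconstructed as r = sign(slope)·√R² (exactly the identity that links the
published R² table to correlation comparisons).

`compare_dependent_correlations` tests r₁ = r(j,k) against r₂ = r(h,m)
measured on the same n units with no shared variable (non-overlapping
dependent correlations): Dunn & Clark's z on the Fisher transforms,
z = (z₁ − z₂)·√((n−3)/(2−2c)), where c is the asymptotic correlation of the
two sample correlations from the Pearson–Filon covariance, computed from
the four cross-correlations r_jh, r_jm, r_kh, r_km (the supplied 4 × 4
matrix must be positive semidefinite). When the cross-correlations are
unknown the two correlations are treated as independent — conservative
whenever their true covariance is positive, the typical case here — and the
result is flagged (`assumed_independent`). The implementation is validated
against a within-eye permutation oracle (sector pairs swapped per eye) to
±0.02 at 5000 permutations, and by closed-form edge cases (r₁ = r₂ ⇒ p = 1;
antisymmetry under swapping).

## Synthetic data

**Angiograms** (`generate_angiogram`) emulate the geometry the
quantification acts on, not acquisition physics. On the native grid:

* a dark disc analog (radius 0.75 mm) at the center;
* `n_major_vessels` (default 8) smooth radial vessels with a
  steep-shouldered super-Gaussian cross-profile (order 4; flat lumen, sharp
  walls — decorrelation images of resolved vessels are closer to top-hat
  than Gaussian) whose caliber (default 100 µm) is the full width at half
  maximum; the ground-truth vessel mask is the supra-half-maximum region;
* capillary texture: curvilinear strokes following a near-radial
  orientation field in near-parallel bundles (the RPC run radially in
  parallel), rasterized as continuous bands 1.2 or 2.2 native px wide with
  an enforced one-pixel inter-capillary gap (8-neighborhood inhibition with
  greedy placement of parallel siblings) and a one-pixel perivascular
  capillary-free zone. Strokes are added until the target area fraction of
  the eligible region (outside vessels and disc) is met; the realized
  fraction is reported exactly from the returned mask and is within ±0.02
  of the request (spaced packing saturates near 55%, above which a small
  unspaced remainder is filled);
* intensity levels background 0.32, capillary 0.76, vessel peak 0.84, disc
  0.10, plus white Gaussian noise (default SD 0.04) and clipping to [0, 1].
  The levels are calibrated so that, after the 1%/99% stretch, the 0.55
  global threshold falls near the midpoint of the capillary edge transition
  — i.e. the images sit on the vendor-normalized intensity scale that fixed
  published thresholds presuppose. The modest vessel-to-capillary
  brightness ratio mirrors the saturation of decorrelation signals at high
  flow.

For OS laterality the entire layout is the horizontal mirror of the OD
layout from the same seed. Everything is deterministic given the spec and
seed.

What the generator does **not** emulate: speckle statistics of SSADA,
projection and motion artifacts, signal-strength gradients, capillary
dropout patterns with spatial disease structure, or a visible
scleral-rim/disc-margin texture. Passing recovery tests therefore shows the
pipeline measures what it claims on resolvable capillary patterns of known
area fraction; it does not certify accuracy on pathological scans.

**Cohorts** (`generate_cohort`) draw two eyes per subject for four groups
(healthy control, NAION, unaffected fellow, POAG), with published group
summaries (means/SDs of age, axial length, visual-field MD, global and
quadrant RNFL, whole/annular/sector PCD) as default parameters and group
sizes 39/16/16/21 subjects ≈ the published 77/31/31/42 eyes. Each eye-level
outcome decomposes as √ρ·(subject effect) + √(1−ρ)·(eye effect) with
ρ = `within_subject_rho` (default 0.4, a mid-range value for inter-eye
correlation of ocular measurements). For each sector, the PCD and RNFL
latents are drawn jointly with the target correlation at both the subject
and the eye level, so the marginal Pearson correlation equals the target —
by default √R² of the published pooled univariate fits (0.755, 0.424,
0.678, 0.469 for S/N/I/T). The same sector correlations apply within every
group; pooled-across-group correlations will differ from the within-group
targets whenever group means differ (an intentional property of pooled
analyses, visible in the analysis output). Values are clipped to physical
ranges (PCD ∈ [0, 100], RNFL ≥ 1 µm, axial length ≥ 15 mm, age ≥ 18);
clipping rather than resampling keeps the latent correlation structure
exact, and at the default parameters the clip probability is at most a few
percent in one tail (NAION temporal RNFL). The fellow group is simulated as
an independent subject pool, not as the literal other eyes of the NAION
subjects; analyses that rely on NAION–fellow pairing across groups are out
of scope. Whole-PCD and MD are generated independently within group, so
the PCD–MD regression in the analysis report has no injected effect.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the image pipeline at the
study geometry (304 px native, ×6 resize, four capillary fractions
0.10–0.55), the replicate study of group contrasts at 100 replicates of the
study-matched cohort, sector-correlation recovery at 5000 eyes per group,
and the permutation oracle at 5000 draws with n = 1000 eyes — sizes at
which every check completes in seconds to a couple of minutes on one CPU.
Percentile definition is NumPy's linear interpolation; box means use
`uniform_filter` with mirror padding; distance transforms and skeletons are
SciPy/scikit-image. Bonferroni corrections are min(1, m·p). Random draws
use `numpy.random.default_rng` seeded per call; identical spec + seed gives
bit-identical images and tables.

## Known limitations

* The vessel-removal algorithm is this package's design (caliber on the
  skeleton, extent gating, disk-union reconstruction); the original custom
  program is unspecified, so absolute PCD values can differ from other
  implementations even at identical thresholds.
* Mixed-model inference is large-sample; for very small cohorts a
  denominator-df method would be preferable.
* Whether the adaptive threshold should see grayscale-AND-global (as here)
  or re-threshold the binary is ambiguous in prose descriptions of such
  pipelines; both orderings share the stated stage order, and the chosen
  reading is the one under which the step is well-defined.
* The synthetic texture is resolvable by construction near the packing
  limit (~55% area); real pathological dropout and flow artifacts are not
  modeled, so recovery bounds measured here are best-case.
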