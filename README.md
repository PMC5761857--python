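# pcdquant

Peripapillary capillary density (PCD) quantification from en-face OCT
angiography, with the downstream cohort statistics used to compare optic
neuropathies.

## The problem

The radial peripapillary capillaries (RPC) are the superficial capillary bed
inside the retinal nerve fiber layer (RNFL) that perfuses retinal ganglion
cell axons. Both non-arteritic anterior ischemic optic neuropathy (NAION)
and primary open-angle glaucoma (POAG) damage those axons, and OCT
angiography (OCT-A) can image the RPC non-invasively on a 4.5 × 4.5 mm
en-face scan centered on the optic nerve head (ONH). Comparing capillary
density between such conditions requires (a) a reproducible way to turn a
grayscale angiogram into a *capillary* map — excluding the large retinal
vessels, which do not represent the microvasculature — and (b) statistics
that respect the paired-eye structure of ophthalmic cohorts.

`pcdquant` implements both stages as a tested, scriptable pipeline, plus a
synthetic-data module that generates angiograms with known ground truth and
cohorts with a prescribed statistical structure, so the whole pipeline is
verifiable without patient data.

## The method

**Quantification** (per eye). The angiogram *I* is upsampled ×6 (bilinear),
contrast-stretched so the 1st/99th intensity percentiles map to 0/1, and
binarized globally at *I* > 0.55. Major vessels are removed from the binary
map: local caliber is measured as 2·EDT along the skeleton (EDT = Euclidean
distance transform), skeleton runs with caliber > 40 µm spanning ≥ 1 mm are
reconstructed into vessel bodies and dilated by 2 px. A local adaptive
threshold (15 × 15 px sampling window, strict ">" against the local mean,
vessel pixels excluded) is ANDed in, giving the perfused-capillary map

&nbsp;&nbsp;&nbsp;&nbsp;capillary = (I_s > 0.55) ∧ (I_s > mean₁₅ₓ₁₅(I_s)) ∧ ¬vessel.

PCD of a region is 100 · |capillary ∩ region| / |region ∖ vessel| (%), with
regions: the whole frame minus the inner 1.95-mm circle; the annulus between
concentric 1.95/3.45-mm circles (0.75 mm wide, matching the standard
circumpapillary RNFL scan circle); and its four 90° quadrants
(superior/nasal/inferior/temporal, nasal–temporal mapping by eye
laterality). A color-coded density map evaluates PCD in 16 × 16-px windows
with 8-px overlap.

**Cohort statistics.** Group differences are tested with a linear mixed
model (fixed group + age, sex, axial length; random subject intercept for
the inter-eye correlation) with Bonferroni-corrected pairwise contrasts;
within-group sector differences with paired contrasts over the six sector
pairs; structure–function association with univariable regressions of
sectoral PCD on sectoral RNFL thickness (reporting R² and r = sign(b)·√R²);
and differences between two dependent, non-overlapping correlations —
e.g. r(PCD_sup, RNFL_sup) vs r(PCD_inf, RNFL_inf) on the same eyes — with
Dunn & Clark's Fisher-z statistic using the Pearson–Filon covariance.

## Worked example

```python
from sklearn.pipeline import Pipeline
from pcdquant import (AngiogramSimSpec, CapillarySegmenter, PCDQuantifier,
                      generate_angiogram)

img, truth = generate_angiogram(AngiogramSimSpec(capillary_fraction=0.40, seed=11))
pipe = Pipeline([("segment", CapillarySegmenter()), ("quantify", PCDQuantifier())])
row = pipe.fit([img]).transform([img]).iloc[0]
print(f"true capillary fraction: {truth.capillary_fraction:.3f}")
print(f"whole-image PCD: {row.pcd_whole_pct:.1f}%")
print(f"whole-annulus PCD: {row.pcd_annulus_pct:.1f}%")
print(f"sectors S/N/I/T: {row.pcd_sup_pct:.1f} / {row.pcd_nas_pct:.1f} / "
      f"{row.pcd_inf_pct:.1f} / {row.pcd_temp_pct:.1f} %")
```

prints

```
true capillary fraction: 0.400
whole-image PCD: 37.5%
whole-annulus PCD: 38.5%
sectors S/N/I/T: 40.7 / 35.4 / 35.1 / 42.8 %
```

The synthetic eye was drawn with 40% of its eligible area covered by
capillaries; the measured annular PCD (38.5%) recovers that fraction to
within a couple of percentage points after resizing, thresholding and
major-vessel removal, and the four sector values scatter around it.

The same pipeline runs from the shell:

```bash
pcdquant simulate-image --out-dir work/images --n 10 --seed 1
pcdquant quantify work/images --out-dir work/quantified
pcdquant simulate-cohort --out work/cohort.csv --seed 1
pcdquant analyze work/cohort.csv --out-dir work/analysis
```

`quantify` writes one CSV row per eye plus a color-coded density-map PNG;
`analyze` writes group-comparison, sector-contrast, regression and
correlation-difference tables plus a text report. CSV schemas are documented
in `docs/schema.md`. All thresholds and geometry are configurable
(`--global-threshold`, `--adaptive-window`, `--vessel-caliber-um`,
`--inner-mm/--outer-mm`, or a YAML config file); defaults are the published
values.

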