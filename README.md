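# psmdkit

Quantitative toolkit for the **peak width of skeletonized mean diffusivity
(PSMD)** — a fully automated diffusion-MRI marker of cerebral small vessel
disease (SVD) — together with the marker battery it is validated against:
threshold-based white matter hyperintensity (WMH) segmentation,
semi-quantitative SVD rating schemas and the total SVD burden score, and the
statistical stack (robust regression, dominance/relative-weights importance,
DeLong ROC comparison) used to relate these markers to each other and to
cognition.

It is aimed at neuroimaging researchers who want a tested, reproducible
implementation of this analysis chain that runs on template-space volumes
(NIfTI) and subject tables (CSV), plus a synthetic phantom/cohort generator
so every stage can be exercised and validated without access to patient
data.

## The statistic

With MD the mean-diffusivity map, FA the fractional-anisotropy map and *S*
the binary white-matter skeleton on a common template grid, the masked
skeleton multiset is

```
V = { MD(v) : v ∈ S, FA(v) ≥ 0.2 }
```

(the FA ≥ 0.2 mask removes CSF-contaminated voxels) and

```
PSMD = P95(V) − P5(V)
```

the difference between the 95th and 5th percentile of the masked skeleton MD
values (percentiles by linear interpolation at rank 1 + (n − 1)q). Wide
peaks mean heterogeneous, diffusely damaged white matter. Regional PSMD
repeats the histogram analysis within each lobar atlas label.

Around it the package implements:

* **WMH quantification** — lesion mask = in-brain FLAIR voxels with
  intensity strictly greater than 1.40 × the modal intensity; partition into
  periventricular (within 10 mm of the ventricles) vs deep WMH and into
  lobes; volumes normalized as % of total intracranial volume and
  square-root transformed.
* **SVD ratings** — Fazekas PVH/DWMH (0–3), EPVS grades (0–4, bins
  none/1–10/11–20/21–40/>40; dichotomous midbrain), microbleed and lacune
  counts (lacunes admitted at 3–15 mm diameter), and the 0–4 SVD burden
  score (one point each for Fazekas PVH = 3 or DWMH ≥ 2; EPVS-BG ≥ 2; ≥ 1
  lacune; ≥ 1 microbleed), with missing modalities propagating as missing.
* **Statistics** — Huber IRLS robust regression, percentage-bend robust
  correlation, Fisher r-to-z contrasts, general dominance weights (full
  subset enumeration) and Johnson relative weights (both decompose model
  R²), Mann–Whitney AUC with DeLong's test for paired ROC curves, and
  Holm–Bonferroni correction.
* **Study pipeline** — cohort-level batteries producing tidy CSV analogs of
  a marker-validation study's association, importance, regional-correlation
  and ROC tables, deterministic at a fixed seed.

## Worked example

```python
from psmdkit import PhantomSpec, generate_phantom, compute_psmd

spec = PhantomSpec(grid_shape=(96, 96, 96), target_psmd=5.51e-4,
                   skeleton_fraction=0.32, seed=1)
res = compute_psmd(generate_phantom(spec).bundle)
print(f"PSMD = {res.psmd:.6g} mm^2/s over {res.n_voxels} voxels")
# PSMD = 0.000550524 mm^2/s over 104230 voxels
```

The phantom plants a skeleton MD distribution whose 95th−5th percentile
spread is 5.51 × 10⁻⁴ mm²/s; the measurement chain recovers 5.505 × 10⁻⁴
(0.09% off) from 104 230 skeleton voxels.

```python
from psmdkit import CohortSimParams, generate_cohort
from psmdkit.stats import importance_analysis

markers = ["wmh_transformed", "epvs_bg", "microbleeds_total", "lacunes_total"]
df = generate_cohort(CohortSimParams(seed=1))          # 145 subjects
res = importance_analysis(df["psmd"], df[markers].to_numpy(), names=markers)
print(res.to_frame().round(4))
#            predictor    beta  relative_weight  pct_contribution  dominance_weight
# 0    wmh_transformed  0.7899           0.5432           89.7419            0.5438
# 1            epvs_bg -0.0510           0.0345            5.6982            0.0347
# 2  microbleeds_total  0.0812           0.0078            1.2877            0.0076
# 3      lacunes_total -0.0008           0.0198            3.2723            0.0193
```

WMH volume carries by far the largest dominance and relative weight for
PSMD (R² = 0.605): the decomposition recovers the generative structure of
the simulated cohort, in which WMH is the dominant PSMD driver.

Command-line equivalents:

```bash
psmdkit simulate --out sim/ --seed 3                  # phantom NIfTIs + cohort CSV
psmdkit psmd --md md.nii.gz --fa fa.nii.gz --skeleton skel.nii.gz \
             --atlas lobes.nii.gz --out psmd.json
psmdkit wmh  --flair flair.nii.gz --brain-mask mask.nii.gz \
             --ventricles vent.nii.gz --atlas lobes.nii.gz --out wmh.json
psmdkit run-study --seed 4 --out study/               # full battery, 13 CSV tables
```

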