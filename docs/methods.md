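# Methods

## The peak-width statistic

PSMD summarises the dispersion of mean diffusivity (MD) over the white-matter
skeleton. The package consumes template-space volumes: an MD map (mm²/s), an
FA map and a binary skeleton on one grid. Registration, skeleton projection
and tensor fitting are upstream of this package and out of its scope; the
statistic itself depends only on the masked value multiset, which is why a
synthetic skeleton of axis-aligned sheets is a valid test substrate.

Conventions that published descriptions leave implicit are fixed here:

* **Percentile rule** — linear interpolation between order statistics at
  rank `1 + (n − 1) q` (numpy's default). On the multiset {1, …, 100} this
  gives P95 = 95.05, P5 = 5.95, peak width 89.1.
* **FA mask** — skeleton voxels enter iff FA ≥ 0.2 (inclusive, the TBSS
  convention). Subject-skeleton and template-skeleton masks compose into one
  boolean conjunction because all inputs are already on the template grid.
* **Summary SDs** — n − 1 denominator over the same masked multiset.
* **Degenerate voxels** — non-finite MD values are excluded with a logged
  count; negative MD values are retained with a warning (they indicate an
  upstream problem but belong to the multiset as defined). An empty
  post-masking multiset raises rather than returning NaNs.
* **Regional estimates** — regions with fewer than 100 surviving skeleton
  voxels (default, configurable) are reported as missing together with the
  observed count, instead of returning a noisy width.

## WMH segmentation

The lesion map is `{v in brain : I(v) > 1.40 × mode}` with a **strict**
inequality, treating the published "more than 1.40 times" cut-off literally.
The modal intensity is estimated by a fixed 256-bin histogram spanning the
in-mask [min, max], ties broken toward the lower bin; a constant image
returns that constant. The threshold factor k = 1.40 is a free parameter: it
was presumably tuned to one scanner's FLAIR contrast and no transferability
is claimed.

Periventricular vs deep WMH is a distance rule: lesion voxels within 10 mm
(Euclidean, via a sampled distance transform) of any ventricle voxel are
periventricular. The literature also contains a connectivity-based
convention; the distance rule was chosen because it is deterministic,
resolution-robust and testable against a brute-force distance oracle. Both
the distance and the threshold factor are arguments, not constants.

Volumes are normalized as percent of total intracranial volume (matching the
magnitude of typical cohort tables, e.g. GM ≈ 39 %TIV, WMH ≈ 0.69 %TIV) and
square-root transformed to tame the right skew of lesion volumes. Expert
manual correction of segmentations is represented as voxelwise override
masks with a logged edit count — the review step has no algorithmic content.

## SVD ratings and burden

The four marker scales are encoded as validated schemas (ranges in the API
docs). Decisions worth stating:

* Lacune diameter bounds 3 and 15 mm are **inclusive** ("minimum/maximum
  of" reads inclusive); the boundary is covered by an explicit test.
* The burden point for EPVS uses basal-ganglia grade ≥ 2, i.e. more than 10
  EPVS ("moderate to severe"); the WMH point uses Fazekas criteria only
  (PVH = 3 and/or DWMH ≥ 2), even when volumetric WMH is also available.
* A missing modality (e.g. no susceptibility-weighted scan, hence no
  microbleed counts) is `None`/NaN, never zero, and propagates to a missing
  burden score. "Possible" microbleeds are kept in an audit field and never
  analysed.

## Statistical stack

**Robust regression** is Huber M-estimation by iteratively reweighted least
squares: weights `min(1, c/|u|)` with tuning constant c = 1.345 (95%
Gaussian efficiency), scale = 1.4826 × MAD of the residuals re-estimated
each sweep, convergence when the maximum coefficient change < 1e-8 (50-sweep
cap; non-convergence is flagged, not raised). Standard errors use the
classical Huber sandwich with the small-sample correction factor, and p
values come from a t distribution with n − p degrees of freedom. At
c → ∞ the fit reduces to OLS (asserted at c = 1e6). Rank-deficient designs
raise an error naming the suspect columns.

**Robust correlation** is the percentage-bend correlation with bend
constant 0.2 (each margin standardised around its percentage-bend location,
residuals beyond the (1 − β) absolute-deviation quantile bent to ±1); the p
value uses the t approximation with n − 2 df. The implementation is checked
against pingouin's independent one to 1e-10.

**Fisher r-to-z** implements the independent-samples closed form
`z = (atanh r1 − atanh r2)/√(1/(n1−3) + 1/(n2−3))`. Contrasts of
correlations sharing a sample (as in the regional matrix) are therefore
approximate; a dependent-correlations test would need the cross-correlation
of the two involved variables.

**Importance decompositions.** General dominance weights average each
predictor's incremental R² over all subsets of the co-predictors within
each subset size, then across sizes — an exact decomposition of the
full-model R², computed by full enumeration (capped at 15 predictors = 2¹⁵
subset fits; the largest model here has 10). Johnson's relative weights use
the symmetric square root of the predictor correlation matrix as the
orthogonal counterpart; they also sum to R². The tabulated "% contribution
to R²" is the relative weight as a share of their sum. Under exact
orthogonality both decompositions collapse to squared zero-order
correlations, which the tests assert.

**ROC/AUC.** AUC is the Mann–Whitney statistic with ties counted ½. DeLong's
test uses placement-value (structural component) variances and covariances;
per-curve 95% CIs are auc ± 1.96√var. A zero-variance difference (e.g. a
score against itself) is flagged degenerate with p = 1 when the AUCs agree.
Score orientation in the ROC battery is explicit per score — pathology
markers point "up" (larger = more impaired), volumes and FA are inverted —
because sign conventions cannot be inferred reliably from data.

**Holm–Bonferroni** is the standard step-down adjustment; correction
families follow the results blocks (the association battery per model is
one family, the 64-cell regional matrix another).

## Synthetic data

**Phantom** (`phantom_forge` role): ellipsoidal brain and ventricle masks;
a skeleton of one-voxel axis-aligned sheets accumulating to the requested
in-brain fraction; skeleton MD ~ Gaussian(md_center, target_psmd/(2·1.6449))
truncated at zero, so the generating 95th−5th spread equals `target_psmd`
exactly; a configurable fraction of skeleton voxels carries FA < 0.2 to
exercise the CSF mask; FLAIR background is a clipped Gaussian with mode
`background_mode` (clipped at 1.30 × mode so that planted lesions at
multiplier ≥ 1.5 are recoverable voxel-exactly at the 1.40 threshold);
lesions are spheres in mm space rasterized by centre-of-voxel inclusion
(analytic volumes for exact-recovery tests); the lobar atlas is the octant
partition of the brain mask. Defaults: 64³ grid, 2 mm isotropic voxels,
md_center 7.7e-4 mm²/s, target_psmd 5.51e-4 mm²/s — typical memory-clinic
cohort means.

**Cohort**: one latent severity per subject (standard normal plus additive
diagnostic-group shifts) drives WMH volume (log-normal, mean ≈ 0.69 ± 0.71
%TIV), microbleed and lacune counts (gamma-mixed Poisson with dispersions
0.054 and 0.115, reproducing heavy overdispersion such as mean 1.44 with
SD 6.3), and EPVS grades (thresholded latents), each loading with
`marker_correlation` (default 0.6 — stipulated, since marker
intercorrelations are not published for such cohorts). Head motion is a
positive log-normal scalar correlated 0.2 with the latent, reproducing the
confounding the head-motion covariate adjusts for. PSMD is linear in
normalized WMH (9e-5 mm²/s per %TIV), microbleed count (2e-6 per bleed) and
motion (3e-5 per unit) plus Gaussian noise (5e-5), centred near 5.5e-4 ±
1.0e-4 mm²/s; ACE-R is linear in PSMD (−6e4 points per mm²/s) and GM volume
(1.2 points per %TIV) plus group shifts and noise (SD 8), truncated to
[0, 100]; MMSE derives from ACE-R. Group proportions default to
33:20:16:23:26:6:21 across control/MCI/AD/PSP/DLB/depression/FTD. The
pre-truncation linear predictor is emitted (`acer_linear`) so the noiseless
generative contract is testable exactly.

Setting all effect slopes to zero yields null cohorts for type-I-error
calibration. Missingness knobs (`n_missing_swi`, `n_missing_wmh_volume`)
default to 0 so the standard batteries run on complete data; listwise
deletion with reported per-model n handles any missingness either way.

What the generators do **not** emulate: scanner physics, registration
error, spatially structured lesion shapes or skeleton anatomy, non-Gaussian
MD tails, rater disagreement, and any nonlinear marker–cognition structure.
Passing tests therefore demonstrate the correctness and calibration of the
measurement and inference chain under the stated generative model — not the
clinical validity of the markers on real data.

## Scenario choices in the calibration tests

* The dominance-recovery check (WMH as the top PSMD predictor) runs under
  the full default cohort, where WMH is generated as the dominant driver.
* The cognition checks (PSMD as top ACE-R predictor and top AUC) run on a
  single-group cohort. Under the multi-group default, diagnostic shifts on
  ACE-R correlate with the latent severity, giving every marker a direct
  path to cognition; the single-group cohort is the configuration in which
  cognition is generated from PSMD and GM alone, which is the ordering
  those checks are about.
* The robust-regression contamination check plants one-sided gross outcome
  errors at the top decile of the predictor, because contamination
  independent of the predictor leaves the OLS slope unbiased and there
  would be no bias to compare.
* Monte-Carlo assertions (type-I error, familywise error) use binomial
  tolerance bands around the nominal level at the stated replicate counts.

## Problem sizes and determinism

Default analyses use 145-subject cohorts and 64³ phantoms (96³ where ≥ 1e5
skeleton voxels are needed); replicate counts are 200–500 for calibration
checks and 2000 for bootstrap/familywise simulations. Every generator and
battery is a pure function of (parameters, seed): `run_study` writes
byte-identical CSVs across runs at a fixed seed, with timestamps confined
to the run log.

## Known limitations

* The robust-fit p values rest on the Wald/t approximation; exact robust
  inference (e.g. bootstrap) is not implemented.
* Dominance enumeration is exponential and capped at 15 predictors.
* The regional Fisher contrasts ignore the dependence of correlations that
  share a sample (see above).
* The PVH/DWMH convention and the k = 1.40 threshold are configurable
  defaults, not claims about other scanners or protocols.
* Phantom anatomy is deliberately schematic; it validates value-level
  computation, not spatial processing.
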