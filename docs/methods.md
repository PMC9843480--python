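# Methods note

This note records the model, procedure, parameter defaults, numerical
choices, and limitations of the `salirad` pipeline. Everything here
describes what the code computes; no empirical claims are made beyond
what the test suite and `scripts/acceptance.py` actually evaluate.

## 1. Analysis model and procedure

Two binary endpoints are analysed at 12 months after radiotherapy:
moderate-to-severe xerostomia (`xer12m`) and moderate-to-severe sticky
saliva (`ss12m`). For each endpoint a **reference** logistic model uses
the pre-treatment symptom grade and the mean dose to the relevant
gland(s); an **extended** model adds one z-normalised CT radiomics
feature. The configured pairings (`PipelineConfig.endpoint_features`)
are:

| endpoint | baseline covariate | dose covariate | added radiomics feature |
|---|---|---|---|
| xer12m | `baseline_xer_grade` | `mean_dose_contra_parotid` | `parotid_sre_2d` |
| ss12m | `baseline_ss_grade` | `mean_dose_bilateral_smg` | `smg_maxhu` |

The added value of the feature is assessed with a likelihood-ratio test
(1 df) between the nested fits; discrimination is summarised by the
apparent AUC of each model's linear predictor. Univariate Wald tests of
each predictor (alone, z-normalised, with intercept) are also reported.

Analyses are repeated in four pre-defined subgroups: all patients;
patients with both submandibular glands (SMGs) intact; patients with
parotid slice-exclusion fraction below 0.5; and patients treated with
the modal fractionation scheme (65 Gy in 30 fractions). A subgroup is
evaluable only if, after listwise deletion of rows with missing model
variables, at least `subgroup_min_n` patients and both outcome classes
remain; otherwise the report states the reason instead of numbers.

## 2. Image processing

**Inputs.** An integer HU volume (valid range −1024…3071) with voxel
spacing, plus one binary mask per gland, on the same grid (NIfTI I/O).

**Artifact slice exclusion.** An axial slice is excluded when *any*
voxel of that slice (anywhere in plane, not only inside the mask)
exceeds `hu_artifact_threshold`. Rationale: metal streaks radiate across
the whole plane, so a bright implant anywhere on the slice contaminates
in-gland texture. If no mask-bearing slice survives, the gland's
features are reported missing (never zero) and its exclusion fraction is
1.0.

**Discretisation.** In-mask HU values on retained slices are clamped to
[−200, 200] and assigned to 16 fixed bins of width 25 HU. Bins are
left-closed/right-open except the top bin, which is closed, so exactly
16 levels occur. Fixed-bin-size (rather than fixed-bin-count)
discretisation keeps the HU meaning of a level constant across patients.
Voxels outside the mask or on excluded slices get label 0 and never
enter any matrix.

**maxHU** is deliberately computed on the *raw, unclamped* HU values of
in-mask voxels on retained slices, since its clinical interpretation
(calcifications, dense inclusions) lives above the texture window.

## 3. Texture matrices and features

**GLCM** (grey-level co-occurrence): counts of ordered label pairs at a
fixed offset, accumulated in both orderings (`counts + counts.T`), i.e.
the symmetric convention; probabilities are counts divided by total
pairs.

**GLRLM** (grey-level run-length): `r(i, j)` counts maximal runs of
level *i* with length *j* along lattice lines in the given direction;
runs are broken by label changes, by unlabelled (masked-out) voxels, and
by the grid boundary.

Features: `SRE = (1/N_r) Σ r(i,j)/j²` and
`IDM = Σ p(i,j)/(1+(i−j)²)`. Both implementations are verified against
exhaustive-enumeration oracles and analytic limits in the test suite.
New (matrix, function) features can be added via
`salirad.texture.register_feature`.

**2D mode** (the default, artifact-robust mode): per retained slice and
per in-plane direction (1,0), (1,1), (0,1), (−1,1), a matrix fragment is
built and the feature evaluated; the gland value is the *unweighted*
mean over all non-empty fragments. Empty fragments (no pairs/runs, e.g.
a single-voxel slice for a pair-based feature) are skipped rather than
counted as zero. Unweighted averaging follows the common slice-wise
radiomics convention; it makes thin slices count as much as thick ones,
which is accepted as part of the feature definition.

**3D mode**: one matrix per direction over the whole (bbox-cropped)
ROI, for the 13 unique directions of the 26-neighbourhood; the feature
is averaged over directions. 3D mode refuses ROIs with any excluded
slice — mixing excluded slices into volumetric runs would silently
reintroduce artifact voxels. A direction is skipped as *geometrically
degenerate* when the ROI bounding box cannot host a line of ≥ 2 voxels
along it; consequently a single-slice ROI in 3D mode reduces exactly to
the average over the four in-plane directions.

The 2D-vs-3D agreement study computes the Pearson correlation of the
two SRE variants over artifact-free parotids (evaluable from 3 pairs).

## 4. Statistical machinery

- z-normalisation: `(x − mean) / sd` with `ddof=1`, NaN-aware; a
  zero-variance feature raises `DegenerateFeatureError` rather than
  returning NaNs. With `normalise_within_subgroup=True` (default),
  features are standardised within each analysed subgroup.
- Logistic fits: Newton–Raphson (tolerance 1e-8, max 100 iterations)
  with a BFGS fallback flagged `converged=False` (typical under perfect
  separation). Deviance is −2·log-likelihood (saturated log-likelihood
  is 0 for binary data).
- LRT: requires strict nesting by predictor-name sets and identical n;
  the statistic is clipped at 0 (tiny negative values are numerical
  noise; values below −1e-6 raise).
- AUC: tie-corrected Mann–Whitney statistic from midranks,
  `(R₁ − n₁(n₁+1)/2)/(n₁ n₀)` — apparent (resubstitution) performance;
  no cross-validation or optimism correction is performed.
- Bilateral SMG features are pooled as the row-wise mean of the left and
  right gland values (`smg_pooling="mean"`); with one gland resected,
  the remaining gland's value is used.
- Baseline grades enter numerically (0–4) by default;
  `baseline_encoding="binary"` dichotomises at grade ≥ 3.

## 5. Synthetic cohort generator

The generator exists so the full pipeline — imaging, texture, exclusion,
modelling — can be exercised and statistically calibrated without
clinical data. Its defaults describe the intended study population.

**What it emulates.**

- *Doses*: per-patient mean gland doses drawn from a monotone PCHIP
  interpolant of the quantile function anchored at (0, 0 Gy), the three
  quartiles, and (1, 70 Gy). Defaults: contra-lateral parotid quartiles
  14.6 / 29.2 / 34.9 Gy; bilateral SMG 47.2 / 56.4 / 59.5 Gy. A
  quantile-function interpolant was chosen because no standard
  two-parameter (or truncated/split normal) family reproduces the
  strongly asymmetric parotid quartiles on [0, 70].
- *Glands*: ellipsoids (parotid diameters 20–40 mm, SMG 15–30 mm) at
  fixed anatomical stations in an 80×80×28 volume with spacing
  1.074×1.074×3.0 mm. Gland interiors carry correlated Gaussian HU
  texture (smoothed white noise; in-plane correlation length log-uniform
  on 0.4–2.5 voxels, through-plane smoothing sigma 0.5 slices; mean
  30 HU, sd 20 HU), background N(20, 8) HU. Shorter correlation length
  means finer texture and higher SRE, giving a controllable
  ground-truth texture axis.
- *Artifacts*: with patient probability 0.95, random axial slices
  (per-slice rate 0.18, at least one if flagged) receive a 3000 HU
  streak crossing the full plane — sufficient to trigger slice
  exclusion, which is the property the pipeline must handle.
- *Clinical variables*: baseline grades drawn with
  P(0..3) = (0.70, 0.24, 0.05, 0.01) (6 % moderate-to-severe);
  SMG resection probability 0.12 per side; fractionation mix
  65 Gy/30 fx 73 %, 60/30 22 %, 70/35 3 %, 55/20 1 %, 50/20 1 %.
- *Outcomes*: logistic in dose (default coefficient 0.08 per Gy),
  baseline grade (0.5 per grade), and a standardised texture truth
  (default coefficient 0 — the null). The intercept is calibrated by
  root-finding so the expected prevalence matches the targets (48 %
  xer12m, 33 % ss12m); it can be pinned explicitly for
  parameter-recovery studies.
- *Reproducibility*: all randomness descends from one seed via
  `numpy.random.SeedSequence` spawning; identical seeds give
  byte-identical cohorts, feature tables, and reports (up to the report
  timestamp).

**What it does not emulate.** No real anatomy (glands are ellipsoids at
fixed centres); no beam-hardening physics (streaks are flat 3000 HU
bands, not physically rendered artifacts); no spatial dose distribution
(dose is a per-gland scalar, not a 3D field, so no dose–texture spatial
interaction); no inter-gland HU correlation within a patient; no
longitudinal symptom dynamics, dropout, or measurement error in grading.
Calibration tests therefore validate the *statistical machinery*, not
clinical effect sizes.

## 6. Numerical and validation choices

- Matrices are built vectorised (array shifts for GLCM; lattice-line
  enumeration plus run-length encoding for GLRLM) and checked for exact
  equality against naive enumeration oracles on hundreds of random
  masked slices; features match oracles to 1e-12 and analytic
  closed-form limits to machine precision.
- Null calibration: over 1000 simulated cohorts with zero texture
  effect, the LRT rejection rate at α = 0.05 is required to lie within
  0.05 ± 0.02 and the univariate p-values to pass a
  Kolmogorov–Smirnov uniformity check.
- Parameter recovery: over 500 cohorts of n = 2000 with a planted
  0.08 /Gy dose effect, every coefficient's Monte-Carlo bias must stay
  below 3 standard errors of its mean.
- The AUC implementation is checked against a closed-form binormal
  value and (in tests only) cross-checked against an independent
  library implementation.
- Problem sizes in the validation suite (cohort sizes, replicate
  counts, tolerances) are the package's own choices, sized so the suite
  completes in about a minute on one CPU.

## 7. Configuration and open design decisions

All thresholds live in `PipelineConfig` (YAML-serialisable, validated,
hashed into the report metadata):

| parameter | default | why |
|---|---|---|
| `hu_artifact_threshold` | 2000 HU | above dense bone, below metal; must exceed the 200 HU discretisation ceiling |
| `subgroup_min_n` | 20 | below this, a 3-parameter logistic fit is unreliable |
| `exclusion_fraction_cut` | 0.5 | "low-exclusion" subgroup keeps parotids with a majority of slices retained |
| `alpha` | 0.05 | conventional significance level for flagging |
| `normalise_within_subgroup` | true | coefficients comparable across subgroups of different scale |
| `baseline_encoding` | numeric | retains ordinal information; binary option for sensitivity analysis |
| `smg_pooling` | mean | one feature per patient from paired glands |

Decisions that reasonable alternatives exist for, kept configurable or
documented rather than hidden: the endpoint/feature pairing
(configurable), slice-wide versus in-mask artifact detection (slice-wide
chosen, see §2), unweighted versus pair-count-weighted fragment
aggregation (unweighted chosen), and the geometric degenerate-direction
rule in 3D (chosen so the 3D mode degrades gracefully to 2D on flat
ROIs).

## 8. Limitations

- Apparent AUC overstates out-of-sample discrimination; no internal
  validation (bootstrap/cross-validation) is implemented.
- The 2D feature average weights slices and directions equally
  regardless of how many runs/pairs each contributes.
- Listwise deletion assumes missingness unrelated to outcome; with
  artifact-driven missingness this may not hold, which is precisely why
  results are reported per subgroup including the low-exclusion stratum.
- Synthetic calibration cannot detect mis-specification that only real
  anatomy or real artifact physics would expose.
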