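# salirad

Artifact-aware CT radiomics of the salivary glands, and nested logistic
models of late radiation-induced toxicity.

## The problem

Head-and-neck radiotherapy frequently damages the salivary glands, leaving
patients with chronic dry mouth (xerostomia) or sticky saliva a year after
treatment. Radiomics studies have reported that pre-treatment CT texture of
the glands — beyond mean gland dose and baseline symptoms — carries
predictive signal for these endpoints: Short Run Emphasis (SRE) of the
contra-lateral parotid for 12-month xerostomia (Xer12m), and maximum CT
intensity (maxHU) of the submandibular glands for sticky saliva (SS12m).
Testing whether such findings transport to a new cohort is hard in
practice: most patients have dental implants whose metal streak artifacts
corrupt individual axial CT slices, so texture must be computed
slice-wise in 2D with artifacted slices excluded, rather than in 3D over
the whole gland.

`salirad` implements that analysis chain as a tested, reusable pipeline:

- **imaging**: HU volumes + binary gland masks (NIfTI), exclusion of any
  axial slice whose in-plane maximum exceeds an artifact threshold
  (default 2000 HU), and discretisation of in-mask intensities into 16
  fixed bins of 25 HU spanning [−200, 200] HU;
- **texture**: grey-level run-length and co-occurrence matrices per
  retained slice in the four in-plane directions, averaged over all
  non-empty (slice, direction) pairs, plus a 13-direction 3D mode for
  artifact-free glands;
- **modelling**: per-endpoint logistic models — reference
  (baseline grade + mean gland dose) versus extended (+ one z-normalised
  radiomics feature) — compared by likelihood-ratio test and apparent AUC;
- **cohort**: a fully parameterised synthetic cohort generator (textured
  ellipsoidal glands, planted artifact slices, calibrated dose and
  prevalence distributions, known ground truth) so the entire pipeline is
  testable without clinical data;
- **pipeline / CLI**: subgroup analyses, the 2D-vs-3D SRE agreement
  study, and deterministic JSON/CSV/markdown reports.

## The statistics

For a grey-level run-length matrix `r(i, j)` (level *i*, run length *j*,
`N_r` runs) and a symmetric co-occurrence matrix with probabilities
`p(i, j)`:

    SRE  = (1/N_r) * sum_ij r(i,j) / j^2            (1 iff all runs have length 1)
    IDM  = sum_ij p(i,j) / (1 + (i-j)^2)            (inverse difference moment; 1 if homogeneous)

maxHU is the maximum raw (unclamped) HU inside the mask on retained
slices. Features are z-normalised across the analysed patients. For
nested logistic fits with log-likelihoods `ll_ref` and `ll_ext`, the
likelihood-ratio statistic `2(ll_ext − ll_ref)` is referred to a
chi-square law with 1 df; the AUC is the tie-corrected Mann–Whitney rank
statistic evaluated on the whole analysis set (apparent performance, no
cross-validation).

## Worked example

```python
from salirad.cohort import CohortSpec, generate_cohort
from salirad.pipeline import run_extraction, run_analysis

data = generate_cohort(CohortSpec(n_patients=40, seed=7))
features = run_extraction(data.patients)
report = run_analysis(features, data.records, seed=7)

frag = [f for f in report["models"]
        if f["endpoint"] == "xer12m" and f["subgroup"] == "all_patients"][0]
print(f"n = {frag['n']}, events = {frag['events']}")
print(f"AUC reference  = {frag['auc_reference']:.3f}")
print(f"AUC + SRE      = {frag['auc_extended']:.3f}")
print(f"LRT p (SRE)    = {frag['lrt_p']:.3f}")
agree = report["sre_2d_vs_3d"]
print(f"2D-3D SRE Pearson r = {agree['pearson_r']:.3f} on {agree['n_glands']} parotids")
```

prints

```
n = 40, events = 17
AUC reference  = 0.824
AUC + SRE      = 0.834
LRT p (SRE)    = 0.448
2D-3D SRE Pearson r = 0.993 on 11 parotids
```

Read: on this synthetic cohort the dose + baseline reference model
already discriminates well (AUC 0.824); adding parotid SRE moves the
apparent AUC to 0.834, a gain the likelihood-ratio test does not support
(p = 0.448) — as expected, since this generator draws outcomes with a
zero texture coefficient. The 2D slice-averaged and 3D volumetric SRE
agree closely (r = 0.993) on the artifact-free parotids.

The same chain is available from the shell:

```bash
salirad simulate --n 109 --seed 1 --out cohort/
salirad extract  --cohort cohort/ --out features.csv
salirad analyse  --features features.csv --clinical cohort/clinical.csv --out analysis/
salirad report   --analysis analysis/report.json --out summary.md
```

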