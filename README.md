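# mriq — ROI-cube SNR/CNR quality metrics for structural MRI

Open-access neuroimaging databases differ enormously in acquisition —
voxel sizes from 0.25 to 1.2 mm, field strengths of 3 T and 7 T, scan
times from minutes to the better part of an hour. Researchers choosing
among them need comparable, protocol-independent measures of image
quality. `mriq` implements such a measurement and inference pipeline
for structural MR volumes, together with a synthetic phantom cohort
generator so that every stage can be exercised and validated without
downloading any imaging data.

## The measurement

For each volume, a 3×3×3 cube of voxels is sampled around a supplied
centre voxel in the corpus callosum (CC, white matter) and in each
caudate nucleus (LCN, RCN; grey matter):

- **SNR** of a structure: μ/σ over the 27 cube voxels (sample SD).
- **Bilateral CN SNR**: the two caudate cubes are pooled into one
  54-voxel sample; SNR is the pooled mean over the pooled SD (this is
  deliberately *not* the average of the two per-side SNRs).
- **CNR** between white and grey matter:

  CNR = (μ_CC − μ_CN) / √(σ_CC² + σ_CN²)

- **Normalization**: because SNR trades off against resolution, ratios
  are divided by the voxel volume (dx·dy·dz mm³). Quantitative maps
  (qT1, qT2\*) are reported raw, since their voxel values are physical
  parameters.
- A **volume-matched** variant scales the cube side by the ratio of
  the cohort's largest voxel size to the image's own, so every image
  is measured over approximately the same physical extent.

On top of the metrics sits the inference layer: paired
frequentist/Bayesian t tests (JZS Cauchy-prior Bayes factors with
scale √2/2, evaluated by adaptive quadrature), scan-time OLS
regressions with Bonferroni adjustment (0.05/2 = 0.025 over the
two-model family), random-intercept linear mixed models for age
effects (null: database intercepts only; full: + continuous age)
compared by a 1-df likelihood-ratio test and a BIC Bayes factor
exp(ΔBIC/2), uniform resampling of interval-reported ages, and
two-group Bayesian reliability comparisons.

## Worked example

The `analysis/` scripts run the full study on a synthetic cohort of 20
databases × 5 subjects (110 volumes including slab/whole-brain pairs
and one interval-age database):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_measure_quality.py
python analysis/03_bilateral_and_scantime.py
python analysis/04_age_effects.py
python analysis/05_reliability.py
```

Step 03 prints, for example:

```
LCN vs RCN (paired over 20 databases): t = -0.855, DF = 19, p = 0.403, BF10 = 0.321
  -> moderate evidence for H0: the nuclei share one SNR distribution, as generated.
snr_cc ~ scan time [pooled]: slope 0.388, adj R2 0.48, p 0.00042 (significant at 0.025)
voxel_volume_mm3 ~ scan time [pooled]: slope -0.000863, adj R2 0.90, p 1.3e-10 (significant at 0.025)
```

The paired test finds no left/right caudate asymmetry (the phantoms
generate both nuclei identically, so BF10 < 1 correctly supports the
null), and the regressions recover the built-in trade-off: longer
scans buy finer voxels and higher normalized SNR. Step 04 reports the
mixed-model age comparisons (mean LRT p and mean BF10 over 1000
interval-age resamples), and step 05 shows Bayes factors ≈ 0.15 for a
second disjoint subject sample, i.e. the five-subject protocol is
reproducible.

The same pipeline runs on real data through the CLI:

```sh
mriq simulate --out cohort/                 # or point at your own NIfTI + CSVs
mriq measure  --manifest cohort/manifest.csv --rois cohort/roi_centers.csv --out run/
mriq analyze  --manifest cohort/manifest.csv --rois cohort/roi_centers.csv --out run/
```

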