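# Methods

## Measurement model

The quality of a structural MR volume is summarised by ratios computed
over small regions of interest: a 3×3×3 voxel cube centred on a
supplied midpoint voxel of the corpus callosum (CC) and of each
caudate nucleus (LCN, RCN). Regional SNR is the cube mean over the
cube standard deviation; the bilateral caudate measure pools the two
27-voxel cubes into one 54-voxel sample and divides the pooled mean by
the pooled SD; and the white/grey contrast-to-noise ratio is

    CNR = (mu_CC - mu_CN) / sqrt(sigma_CC^2 + sigma_CN^2),

with the sign preserved (white minus grey). Because SNR trades off
against resolution, both ratios are divided by the voxel volume
(dx·dy·dz, mm³) for all weighted contrasts; quantitative maps (qT1,
qT2\*) are left raw because their voxel values are physical relaxation
parameters, not arbitrary signal units.

Several conventions here were genuinely open and are our choices:

- **Sample SD (n−1)** everywhere. With n = 27 the difference from the
  population SD is ~2%, identical across all images, so comparisons
  are unaffected.
- **Pooled CN SNR uses the mean, not the literal sum, of the 54
  values.** A literal summed signal over the pooled SD scales the
  ratio by 54 and would put the bilateral SNR on a different scale
  from the CC SNR; the mean keeps the two regional measures
  commensurate. The summed variant is available via `pooling="sum"`.
- **"Dividing by the voxel dimensions" means dividing by voxel
  volume** — the product of the three dimensions is the only scalar
  reading, and dividing by each linear dimension sequentially is the
  same number.
- **Volume-matched cubes**: the side per axis is
  round(3 · reference_dim / own_dim) voxels, then forced *up* to the
  next odd integer so a centre voxel exists. At equal voxel sizes this
  reduces exactly to the contiguous 3×3×3 cube; the odd-forcing
  slightly overshoots the matched physical extent, which we prefer to
  an off-centre cube.
- **Degenerate ROIs (σ = 0) raise errors** rather than returning
  infinity, which would silently poison downstream means and SEMs.

## Synthetic phantom cohorts

The generator emulates the statistical structure a multi-database
quality comparison rests on, not MR physics. Each volume is a uniform
background (default intensity 20) with three disjoint axis-aligned
cuboid structures — CC at intensity 100, the two caudate blocks at 80
(at the reference age) — plus i.i.d. Gaussian noise of SD 5.
Databases (default 20, five subjects each) differ in isotropic voxel
size (evenly spaced over 0.25–1.2 mm), scan time (longer for finer
voxels, ~7–36 min), field strength (7 T below 0.7 mm, else 3 T) and a
Gaussian random intercept (SD 5) added to every structure mean. Ages
are uniform over 18–86 years; structure means drift linearly with age
(defaults −0.1 intensity/yr for CC, −0.3 for the caudates, emulating
the faster grey-matter signal decline) and the noise SD may drift too
(+0.02/yr). The reference age is the midpoint of the age range, so
slopes are centred. One database can be flagged to report 5-year age
intervals instead of point ages, and databases can contribute paired
slab acquisitions, modelled as the same anatomy at half the voxel
size.

What this deliberately does **not** model: Rician noise floors, bias
fields, motion, partial-volume effects, anatomical shape, or any
scanner physics. The measurement only ever touches small cubes well
inside each structure, so cuboids with exact Gaussian noise are the
minimal sufficient emulation — and they keep every estimator's truth
closed-form (SNR → μ/σ, CNR → Δ/(σ√2) for equal-variance regions).
Passing tests therefore validate the estimators and the inference
machinery under the generating model; they say nothing about
robustness to the artefacts real images carry.

A known small-sample property worth stating: the mean of *per-cube*
SNR estimates is biased upward by E[σ/s] at n = 27, about +1.0%
(E[s⁻¹] for a chi-distributed SD), so consistency checks pool the
voxels of many cubes into a single mean/SD, which converges to the
true μ/σ without that bias. The per-cube bias is identical across
images and cancels from comparisons.

## Inference layer

- **Paired t tests** use the classical two-sided statistic with
  df = n−1. Identical samples return t = 0, p = 1 (exactly no
  evidence) rather than an error; a zero-variance *nonzero* difference
  raises, since t is undefined.
- **JZS Bayes factors** place a Cauchy(0, r = √2/2) prior on the
  standardised effect (the "medium" default of the R `BayesFactor`
  package), computed by integrating the g-mixture representation with
  adaptive quadrature on a log-space integrand; relative tolerance
  1e-6, non-convergence raises with diagnostics. The two-group
  (reliability "Bayesian ANOVA") case uses the same integral with
  effective sample size n₁n₂/(n₁+n₂) and df = n₁+n₂−2 — a one-way
  ANOVA with two levels is exactly the squared two-group t.
- **Scan-time regressions** are OLS of the per-database response on
  scan time, fitted pooled and per field-strength stratum; the
  Bonferroni-adjusted threshold over the two-model family is
  0.05/2 = 0.025.
- **Age models** are random-intercept linear mixed models fitted by
  maximum likelihood (never REML — the compared models differ in their
  fixed effects, and REML likelihoods are not comparable across fixed-
  effect structures). Age enters centred and continuous. The LRT is
  χ² on 1 df; tiny negative χ² from optimiser noise (< 1e-6 relative)
  is clamped to zero, anything worse raises. Because `statsmodels`
  mixed-model results expose no BIC, it is computed as
  −2·llf + k·log(n) with k counting fixed effects plus the two
  variance parameters, and the model-comparison Bayes factor is the
  BIC approximation exp((BIC_null − BIC_full)/2). This is a standard,
  fully testable surrogate for a mixed-model g-prior Bayes factor; its
  magnitude is comparable in direction and order, not digit-for-digit,
  with other BF flavours. Evidence labels follow the Jeffreys-style
  bands at 3, 10, 30, 100.
- **Interval ages** are resolved by uniform draws within [min, max]
  and the model comparison repeated (default 1000 iterations), with
  the mean p and mean BF reported alongside the per-iteration arrays.
- **Age groups** for visual summaries are the closed bins young
  [18, 28], middle [34, 53], elderly [63, 86]; ages in the gaps stay
  "unbinned", are excluded from grouped tables, and are retained by
  all continuous-age models.
- The bilateral LCN/RCN test aggregates to **database means** before
  pairing; the aggregation unit is configurable by the caller simply
  by passing different vectors.

## Calibration and recovery experiments

The statistical checks run at sizes chosen to make their Monte-Carlo
error small relative to the tolerance being asserted:

- LRT type-I calibration: 500 null cohorts of 20 databases × 5
  subjects, responses drawn directly from the random-intercept model
  (intercept SD 2, residual SD 3). The rejection rate at nominal 0.05
  lands in [0.03, 0.08] and the p-values pass a KS uniformity test.
  Simulating at the response level rather than synthesising voxel data
  isolates the quantity under test — the LRT's null distribution —
  at a fraction of the cost; the voxel-level path is exercised by the
  recovery experiment below.
- Slope recovery: 100 cohorts of 20 databases × 15 subjects with a
  generating caudate age slope of −0.3 intensity/yr, measured from
  generated volumes through the full cube pipeline (the response is
  the pooled-CN cube mean, whose generating slope is exactly −0.3; an
  SNR response would carry slope −0.3/σ instead). The full model's
  95% CI covers the truth in ≥ 90% of replicates and the LRT prefers
  it in ≥ 80%.
- Estimator consistency: SNR pooled over 10⁵ cubes within 1% of
  100/5 = 20; mean CNR over 10³ volumes within 5% of 20/(5√2).

## Numerical and I/O conventions

Voxel indices are 0-based. The NIfTI header is authoritative for
voxel geometry; a manifest disagreeing by more than 1e-4 mm triggers a
warning and the header wins. Missing scan time or field strength
excludes a scan from scan-time regressions only. All CSVs are UTF-8
with a header row. Volumes are written as NIfTI-1 with an
identity-orientation affine scaled by voxel size; writes are
byte-deterministic, and re-running the pipeline with the same config
and seed reproduces the metrics table byte for byte. Every stochastic
operation takes an explicit seed; cohort generation derives
per-subject and per-scan generators from (seed, database, subject,
contrast, acquisition) tuples so that subsets and disjoint reliability
re-samples are reproducible independently of iteration order.

## Limitations

The phantom world is exactly the model the inference assumes
(Gaussian, linear, homoscedastic within scan) — calibration results
here are a correctness floor, not evidence about real MR data.
Voxel-volume normalization spreads responses over orders of magnitude
across databases with very different resolutions, which inflates
residual heteroscedasticity in pooled mixed models; the random
intercept absorbs level differences but not scale differences. The
BIC Bayes factor is an approximation whose prior is implicit; report
it as a direction-and-order statement. The volume-matched method
assumes the reference voxel is the cohort's largest on every axis and
errors otherwise.
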