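# Methods

## Scope and model

`braingap` estimates an individual's **BMI gap**: the difference between the
body-mass index predicted from whole-brain grey-matter volume (GMV) and the
measured BMI, after correcting the regression-to-the-mean bias of the
predictor. The package implements the full analysis chain on *phantom*
cohorts with known ground truth, because the multi-site clinical MRI cohorts
such analyses are normally run on cannot be redistributed. Every stage is,
however, written exactly as it would be used on real data: the phantom is an
input, not a shortcut.

The analysis chain is

1. **Cohort construction** — inclusion window (age 15–75 years, BMI
   18.5–35 kg/m²), then a discovery sample drawn to approximate a uniform
   BMI distribution over 33 half-open 0.5-kg/m² bins, with within-bin greedy
   quantile matching of age against the pooled age distribution (age and BMI
   are naturally correlated; matching decouples them from the bin
   structure). The remainder forms the validation sample.
2. **Preprocessing chain**, fitted strictly on each training partition:
   optional Gaussian smoothing (mask-renormalized; default FWHM 2 voxels),
   per-voxel OLS residualization of age (residuals re-centred on the
   training voxel mean so predictions stay on the GMV scale), scalar
   per-site global-mean offset correction, PCA retaining a configured
   cumulative explained variance (default 0.80), and per-component min–max
   scaling to [0, 1] with clipping at application time. Linear model weights
   pull back exactly through scaling and PCA to a voxel-space weight vector
   plus constant.
3. **Repeated nested cross-validation** — outer 5 folds × 5 repetitions;
   inside every outer training partition an inner repeated CV selects the
   hyperparameters of an ε-insensitive linear SVR (BMI; inner out-of-fold
   MAE criterion) or a linear SVC with inverse-frequency class weights
   (diagnosis; inner balanced-accuracy criterion). Ties break toward the
   smaller regularization constant. The winning setting is refit on the full
   outer training partition; predictions are recorded only for the outer
   test fold, and out-of-fold predictions are averaged across repetitions.
   Model significance uses label permutation with the CV assignment fixed:
   p = (1 + #{permuted statistic at least as good}) / (1 + n_perm).
4. **Gap correction** — raw gap = predicted − measured BMI. Because any
   regression predictor over-estimates low and under-estimates high values
   of its target, raw gap is regressed on measured BMI by OLS in the
   discovery sample (the only cohort with unbiased out-of-fold predictions)
   and the fitted line is subtracted everywhere with frozen coefficients.
   In the fitting cohort the corrected gap then has mean 0 and zero BMI
   correlation by construction; in transferred cohorts genuine group shifts
   survive.
5. **Voxel maps** — cross-validation ratio (mean member weight / SE) and
   sign-based consistency across the k·r back-projected member weight
   vectors; binarized maps of the BMI and diagnosis models are intersected
   to locate jointly predictive voxels.
6. **Sparse PLS** — penalized rank-1 decompositions of X'Y between a
   six-column clinical matrix (BMI gap, SCZ expression score, PANSS total,
   age of onset, illness duration, hospitalizations) and the overlap-region
   voxel matrix, with soft-threshold/bisection L1 constraints, projection
   deflation, row-permutation LV significance and case-resampling bootstrap
   weight stability.
7. **Weight gain** — weight change at 1- and 2-year horizons, correlation
   scans over threshold (≥3/5/7 % gain), age-window, sex and group filters,
   and a tabular nested-CV classifier of ≥7 % gain (features: BMI gap, age,
   sex, group, exercise, somatic history, tobacco; in-fold median imputation
   and z-scoring only), compared with and without the BMI-gap feature by a
   paired sign-flip permutation test on per-subject correctness.

## The phantom generator

`synthdata` builds a 3-D voxel grid (default 12×12×12 = 1728 voxels) fully
partitioned into Voronoi regions, with two contiguous blob signatures grown
by best-first search: a BMI signature (default 60 voxels, 80 % negative
weights — lower GMV predicting higher BMI) and a disease signature (default
60 voxels) sharing a configurable fraction of its voxels with the BMI blob
(default 50 %, realized within ±1 voxel).

Voxel values are additive: baseline 0.5; per-voxel age slopes
(N(−0.0015, 0.0005) GMV/year); per-voxel sex effects (SD 0.005); scalar
per-site offsets (SD 0.02, 4 sites); a BMI term
β_BMI·(BMI − 24.5 + propensity)·signature with β_BMI = 0.005 per kg/m²; a
disease term per group (SCZ 0.020, CHR 0.008, ROD 0.005); a clinical-latent
term (0.006 per SD) on the overlap voxels; and i.i.d. Gaussian noise
(SD 0.04). Age and BMI are drawn through a Gaussian copula (correlation
0.25, the direction reported for adult cohorts; no published value exists)
with BMI truncated-normal (24.5 ± 3.5, bounded to 18.5–35) and HC ages
uniform over 15–75. Each subject carries a latent **gap propensity**
(kg/m²; group means SCZ +1.05, CHR +0.51, ROD −0.82, SD 1.5) entering the
brain exactly like extra BMI, and — in patients — a 1-D clinical latent
factor loading on PANSS total (0.6), onset (0.5), duration (0.5) and
hospitalizations (0.6). Follow-up weights add γ·propensity (defaults γ₁ =
0.5, γ₂ = 1.0 kg per kg/m², the 2-year coupling at least the 1-year one), a
mild negative age modifier, optional group mean gain, N(0, 3 kg) noise and
missing-at-random dropout (30 % / 50 %).

Effect sizes were fixed once so that standard analyses on default-sized
cohorts (n ≈ 400–600) recover the seeded structure with comfortable
margins — mass-univariate regression recovers ≥90 % of signature voxels at
q < 0.05, and group propensity shifts reappear in corrected gaps. They are
*testability* settings: per-voxel effects are far stronger than in real
morphometry, so passing tests demonstrate correctness of the machinery, not
attainable real-data effect sizes. The phantom also omits spatial noise
correlation (optional smoothing of the noise field exists but defaults to
off), scanner-specific voxel-wise profiles (site effects are scalar), and
any nonlinear age or allometric structure.

A `TruthRecord` stores every systematic component, so tests can verify that
`data − reconstruct_systematic(...)` equals the drawn noise exactly.

## Numerical and inferential choices

* **PCA** uses the exact Gram-matrix eigendecomposition when n ≤ V (much
  faster at these shapes), with a deterministic sign convention
  (largest-|loading| entry positive).
* **SVR targets are centred** before fitting: liblinear regularizes the
  bias, so raw BMI-scale targets converge slowly and bias the intercept;
  the training-mean offset is folded back into the intercept.
* **Sign-consistency calibration.** The exact binomial test on member sign
  counts assumes independent members. CV members share most training
  subjects — and all of them share the cohort — so at a signal-free voxel
  every member inherits the same cohort-level chance correlation: empirically
  ~60 % of null voxels are sign-unanimous and the binomial/BH mask has a
  false-positive rate near 0.6 at any noise level (the effect is a function
  of training-set overlap, not SNR). The binomial consistency, p and q are
  therefore reported as *descriptive* reliability fields, and binarization
  defaults to an empirical-null calibration: the grand-mean weight map is
  standardized by the median and MAD across in-mask voxels (assuming most
  voxels are signal-free), converted to two-sided normal p-values and
  BH-corrected. On the default phantom this yields ~97 % signature recovery
  at a per-voxel false-positive rate < 10⁻³.
* **Map-recovery runs disable smoothing** (`smooth_fwhm = 0`): kernel
  smoothing deliberately spreads signal into the shell around a seeded
  blob, which is correct for prediction but blurs the spatial support
  against which recovery is scored.
* **SPLS** initializes from the leading singular vector of X'Y, iterates
  soft-thresholded power steps with bisection on the threshold (80
  iterations) so the L1 constraint just binds, and stops at successive
  weight changes < 1e-6. Deflation is projection (score-space) on both
  matrices — stabler than Hotelling deflation under sparsity. Only X rows
  are permuted for LV significance (one side suffices to break coupling).
  Clinical standardization uses the analysis sample's own mean/SD: the SPLS
  stage is descriptive, not predictive.
* **Degenerate cases**: constant scaling components contribute zero weight
  in back-projection (logged); zero-variance voxels get age slope 0;
  single-subject sites get a mean-of-one offset (flagged); CV members with
  constant labels are dropped, and a run fails if >20 % of members are
  degenerate; correlation-scan cells below n = 5 report r = NA.

## Problem sizes used in the shipped checks

Tests and the acceptance script run scaled-down designs chosen as the
package's own reference conditions: unit tests use 64–216-voxel grids with
30–300 subjects; calibration checks run 200 seeds at n = 30, 99 label
permutations, 3-fold single-repetition CV and a single hyperparameter;
map-recovery checks use the full 1728-voxel grid with 400 HC + 150 SCZ,
5×5 outer CV and a reduced grid (C ∈ {0.25, 1, 4}, ε = 0.1·SD); the
acceptance pipeline simulates 920 subjects (500 HC / 120 SCZ / 150 CHR /
150 ROD) with a 250-subject discovery sample. Inner repetitions are reduced
(1–2) relative to the 5×5 default where the inner criterion is already
stable.

## Known limitations

* The phantom's linear additive voxel model cannot probe robustness to
  nonlinearity, registration error, or heteroscedastic site noise.
* The empirical-null map calibration assumes the majority of voxels are
  signal-free; dense true signal would shrink its sensitivity.
* Gap correction is linear in BMI only (the documented bias is linear);
  covariate-augmented corrections are deliberately out of scope.
* The SCZ-expression score is a raw decision value; it is comparable
  across subjects within one trained ensemble but not across ensembles.
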