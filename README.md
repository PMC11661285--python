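# braingap

Brain-based BMI-gap estimation on fully synthetic phantom cohorts.

Psychiatric populations carry a two-to-three-fold excess of obesity and
metabolic disease, and structural brain imaging shows reproducible
associations between body-mass index (BMI) and regional grey-matter volume
(GMV). A *normative-gap* analysis turns this into an individual marker:
train a machine-learning model to predict BMI from whole-brain voxel-wise
GMV in healthy controls, apply the frozen model to new individuals, and read
the bias-corrected difference

```
BMIgap = BMI_predicted − BMI_measured   (kg/m²)
```

as how much "heavier" a person's brain looks than their scale says — a
candidate marker for metabolic risk stratification and for predicting future
weight gain in early psychosis and depression. `braingap` implements the
whole analysis as a reusable, tested library for methodologists who want to
study, stress-test or extend such pipelines: the multi-site clinical MRI
cohorts these analyses are built on cannot be redistributed, so the package
ships a first-class phantom-cohort generator with known ground truth
(seeded voxel signatures, latent gap propensities, site/age/sex confounds,
clinical latent factors, longitudinal weights) against which every stage is
validated.

## What is implemented

* `braingap.synthdata` — phantom atlas (contiguous signed BMI and disease
  voxel signatures with a configurable overlap), cohort simulation
  (HC/SCZ/CHR/ROD, multi-site, age–BMI-correlated), longitudinal weights
  coupled to the latent gap propensity, and exact ground-truth records.
* `braingap.cohort` — inclusion windows, 33-bin uniform-BMI discovery
  sampling with within-bin age matching, discovery/validation split.
* `braingap.preprocess` — leakage-free in-fold chain: Gaussian smoothing,
  per-voxel age residualization, scalar site offsets, PCA, 0–1 scaling,
  and exact back-projection of model weights to voxel space.
* `braingap.nestedcv` — repeated nested CV (5×5 outer, repeated inner) for
  ε-insensitive linear SVR (MAE criterion) and class-weighted linear SVC
  (balanced-accuracy criterion), ensemble out-of-fold predictions, external
  application, label-permutation significance.
* `braingap.gap` — raw gap, OLS regression-to-the-mean bias correction
  fitted on discovery out-of-fold predictions and frozen for transfer,
  group summaries.
* `braingap.maps` — cross-validation-ratio and sign-consistency maps with
  calibrated binarization, and BMI×disease map overlap.
* `braingap.spls` — sparse partial least squares (penalized rank-1 SVD with
  L1 soft-thresholding, projection deflation, permutation-tested latent
  variables, bootstrap weight stability, CV sparsity selection).
* `braingap.longitudinal` — 1-/2-year weight change, threshold/age/sex/group
  correlation scans, ≥3/5/7 % weight-gain classifiers with BMI-gap ablation
  and a paired sign-flip model comparison.
* `braingap.pipeline` / `braingap.cli` — config-driven end-to-end runs
  (`braingap run --config cfg.yaml --seed 7 --out runs/demo`).

See `docs/methods.md` for the model, defaults and design rationale.

## Worked example

Train a BMI predictor on phantom controls, transfer it to a schizophrenia
group, and summarize the bias-corrected gap:

```python
import numpy as np
from braingap import synthdata as sd
from braingap.cohort import BinSpec, apply_inclusion, sample_uniform_with_matching
from braingap.nestedcv import make_cv, train_nested, evaluate_regression, apply_ensemble
from braingap.gap import compute_gap, fit_gap_correction, make_gap_table, summarize_gap_by_group
from braingap.preprocess import ChainConfig

atlas = sd.make_phantom_atlas(grid_shape=(6, 6, 6), signature_sizes=(16, 16), seed=0)
cfg = sd.CohortConfig(group_sizes={"HC": 300, "SCZ": 60}, beta_bmi=0.02)
subjects, gmv, truth = sd.simulate_cohort(atlas, cfg, seed=0)

hc, _ = apply_inclusion(subjects[subjects["group"] == "HC"])
split = sample_uniform_with_matching(hc, BinSpec(), total_n=150, seed=0)
disc = np.flatnonzero(subjects["id"].isin(split.ids("discovery")))

cov = subjects[["age", "site"]]
cv = make_cv(len(disc), k=5, r=5, seed=0, inner_k=5, inner_r=1)
ens, pred = train_nested(gmv.select(disc), cov.iloc[disc].reset_index(drop=True),
                         subjects["bmi"].to_numpy()[disc], cv, task="svr",
                         grid={"C": [0.25, 1.0], "epsilon_frac": [0.1]},
                         chain_config=ChainConfig(smooth_fwhm=0), seed=0)
print("discovery:", {k: round(v, 3) for k, v in evaluate_regression(pred).items()})

corr = fit_gap_correction(compute_gap(pred["ensemble"], pred["y_true"]), pred["y_true"])
scz = np.flatnonzero((subjects["group"] == "SCZ").to_numpy())
applied = apply_ensemble(ens, gmv.select(scz), cov.iloc[scz].reset_index(drop=True))
table = make_gap_table(subjects["id"].iloc[scz], subjects["group"].iloc[scz],
                       subjects["bmi"].to_numpy()[scz],
                       applied["ensemble"].to_numpy(), corr)
print(summarize_gap_by_group(table).round(2).to_string(index=False))
```

prints

```
discovery: {'MAE': 1.626, 'R2': 0.683, 'r': 0.861, 'n': 150}
group  n  gap_raw_mean  gap_raw_sd  gap_corrected_mean  gap_corrected_sd
  SCZ 60          1.82        1.69                1.14              0.96
```

The out-of-fold discovery fit (MAE 1.63 kg/m², R² 0.68) confirms the model
learned the seeded voxel signature. The SCZ group was simulated with a
latent gap propensity of +1.05 kg/m²: the raw gap (1.82) over-states it
because of the predictor's regression-to-the-mean bias, while the corrected
gap (1.14 ± 0.96) recovers the seeded shift plus the small contribution of
disease-related GMV loss inside the BMI-predictive pattern.

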