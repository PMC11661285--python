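"""Phantom cohort generator with known ground truth.

Real studies of brain-based BMI prediction work from voxel-wise grey-matter
volume (GMV) maps of thousands of subjects across many scanners.  Those
cohorts are not redistributable, so this module builds *phantom* cohorts on a
small 3-D voxel grid in which every systematic effect is known and
recoverable:

* a :class:`PhantomAtlas` carrying contiguous, spatially structured voxel
  signatures for BMI (predominantly negative: lower GMV with higher BMI) and
  for disease, with a configurable overlap fraction between the two;
* a subject table with group membership (HC / SCZ / CHR / ROD), site, sex,
  age, BMI (truncated to the 18.5-35 kg/m² analysis range and correlated
  with age), baseline weight and — for patients — clinical scores driven by
  a shared latent factor;
* a voxel matrix assembled additively from baseline, age, sex, site, BMI,
  disease and clinical-latent components plus Gaussian noise; and
* a :class:`TruthRecord` sufficient to reconstruct every systematic
  component exactly, so parameter-recovery tests can separate signal from
  the drawn noise.

Each subject also carries a latent *gap propensity* (kg/m² scale): an extra
brain-BMI offset, independent of measured BMI by construction, which is what
a downstream BMI-gap analysis should recover and which optionally couples to
future weight change (:func:`simulate_longitudinal`).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import GMVMatrix

__all__ = [
    "ConfigError",
    "SizingError",
    "PhantomAtlas",
    "CohortConfig",
    "TruthRecord",
    "make_phantom_atlas",
    "simulate_cohort",
    "simulate_longitudinal",
    "reconstruct_systematic",
]

PATIENT_GROUPS = ("SCZ", "CHR", "ROD")


class ConfigError(ValueError):
    """Invalid generator configuration."""


class SizingError(ValueError):
    """Requested signature does not fit in the available region."""


# --------------------------------------------------------------------------
# atlas


@dataclass
class PhantomAtlas:
    """Voxel grid with region labels and signed BMI / disease signatures."""

    grid_shape: tuple[int, int, int]
    region_labels: np.ndarray  # (n_voxels,) int >= 1
    bmi_signature: np.ndarray  # (n_voxels,) float, sparse
    disease_signature: np.ndarray  # (n_voxels,) float, sparse
    overlap_fraction: float
    seed: int

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def bmi_mask(self) -> np.ndarray:
        return self.bmi_signature != 0

    @property
    def disease_mask(self) -> np.ndarray:
        return self.disease_signature != 0

    @property
    def overlap_mask(self) -> np.ndarray:
        return self.bmi_mask & self.disease_mask


def _neighbors(flat: int, shape: tuple[int, int, int]) -> list[int]:
    z, y, x = np.unravel_index(flat, shape)
    out = []
    for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        nz, ny, nx = z + dz, y + dy, x + dx
        if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
            out.append(int(np.ravel_multi_index((nz, ny, nx), shape)))
    return out


def _grow_blob(seeds: list[int], size: int, allowed: np.ndarray,
               shape: tuple[int, int, int], center: np.ndarray,
               coords: np.ndarray) -> np.ndarray:
    """Grow a 6-connected blob of `size` voxels from `seeds`, preferring
    voxels close to `center`.  Raises SizingError if it cannot fit."""
    chosen: list[int] = []
    in_set = np.zeros(allowed.size, dtype=bool)
    heap: list[tuple[float, int]] = []
    seen = np.zeros(allowed.size, dtype=bool)

    def push(v: int) -> None:
        if not seen[v] and allowed[v]:
            seen[v] = True
            d = float(np.sum((coords[v] - center) ** 2))
            heapq.heappush(heap, (d, v))

    for s in seeds:
        if allowed[s]:
            push(s)
        else:  # seed outside the allowed set: start from its neighbours
            seen[s] = True
            for nb in _neighbors(s, shape):
                push(nb)
    while heap and len(chosen) < size:
        _, v = heapq.heappop(heap)
        chosen.append(v)
        in_set[v] = True
        for nb in _neighbors(v, shape):
            push(nb)
    if len(chosen) < size:
        raise SizingError(
            f"signature of {size} voxels does not fit (placed {len(chosen)})"
        )
    return np.asarray(chosen, dtype=int)


def make_phantom_atlas(grid_shape=(12, 12, 12), n_regions: int = 8,
                       signature_sizes=(60, 60), overlap_fraction: float = 0.5,
                       neg_fraction: float = 0.8, seed: int = 0) -> PhantomAtlas:
    """Build a phantom atlas with contiguous BMI and disease signatures.

    Parameters
    ----------
    signature_sizes : (int, int)
        Voxel counts of the BMI and disease signatures.
    overlap_fraction : float in [0, 1]
        Fraction of *disease*-signature voxels shared with the BMI
        signature; realised within +/-1 voxel of ``round(f * size_disease)``.
    neg_fraction : float
        Fraction of signature voxels with negative sign (lower GMV
        predicting the phenotype); default 0.8 for both signatures.
    """
    grid_shape = tuple(int(d) for d in grid_shape)
    if len(grid_shape) != 3 or any(d < 4 for d in grid_shape):
        raise ConfigError("grid_shape must be 3 dimensions, each >= 4")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ConfigError("overlap_fraction must be in [0, 1]")
    size_bmi, size_dis = (int(s) for s in signature_sizes)
    n_vox = int(np.prod(grid_shape))
    if size_bmi > n_vox or size_dis > n_vox:
        raise SizingError("signature size exceeds voxel count")

    rng = np.random.default_rng(seed)
    coords = np.indices(grid_shape).reshape(3, -1).T.astype(float)

    # Voronoi regions around random centres -> every voxel labelled.
    centers = rng.choice(n_vox, size=min(n_regions, n_vox), replace=False)
    d2 = ((coords[:, None, :] - coords[centers][None, :, :]) ** 2).sum(axis=2)
    region_labels = np.argmin(d2, axis=1) + 1

    # BMI signature: ball-like blob inside one region with enough capacity.
    counts = np.bincount(region_labels, minlength=n_regions + 1)[1:]
    eligible = np.flatnonzero(counts >= size_bmi) + 1
    if eligible.size == 0:
        raise SizingError(
            f"BMI signature of {size_bmi} voxels exceeds every region's capacity "
            f"(largest region: {counts.max()})"
        )
    region = int(rng.choice(eligible))
    in_region = region_labels == region
    reg_centroid = coords[in_region].mean(axis=0)
    start = int(np.flatnonzero(in_region)[
        np.argmin(((coords[in_region] - reg_centroid) ** 2).sum(axis=1))])
    bmi_idx = _grow_blob([start], size_bmi, in_region, grid_shape,
                         coords[start], coords)
    bmi_mask = np.zeros(n_vox, dtype=bool)
    bmi_mask[bmi_idx] = True

    # Disease signature: shared core carved out of the BMI blob boundary,
    # remainder grown contiguously outside the BMI blob.
    n_shared = int(round(overlap_fraction * size_dis))
    if n_shared > size_bmi:
        raise SizingError("requested overlap exceeds BMI signature size")
    dis_idx_parts = []
    if n_shared > 0:
        edge = bmi_idx[np.argmax(((coords[bmi_idx] - coords[start]) ** 2).sum(axis=1))]
        shared = _grow_blob([int(edge)], n_shared, bmi_mask, grid_shape,
                            coords[edge], coords)
        dis_idx_parts.append(shared)
        seeds = list(shared)
        grown = np.zeros(n_vox, dtype=bool)
        grown[shared] = True
        allowed = ~bmi_mask & ~grown
        anchor = coords[shared].mean(axis=0)
    else:
        far = int(np.argmax(((coords - coords[start]) ** 2).sum(axis=1)))
        seeds, allowed, anchor = [far], ~bmi_mask, coords[far]
    rest = size_dis - n_shared
    if rest > 0:
        if n_shared > 0:
            # seed frontier from the shared set but never re-enter the BMI blob
            outer = _grow_blob(seeds, rest, allowed, grid_shape, anchor, coords)
        else:
            outer = _grow_blob(seeds, rest, allowed, grid_shape, anchor, coords)
        dis_idx_parts.append(outer)
    dis_idx = np.concatenate(dis_idx_parts) if dis_idx_parts else np.empty(0, int)

    def _signed_weights(idx: np.ndarray) -> np.ndarray:
        w = np.zeros(n_vox)
        mags = rng.uniform(0.8, 1.2, size=idx.size)
        signs = np.ones(idx.size)
        n_neg = int(round(neg_fraction * idx.size))
        neg_at = rng.choice(idx.size, size=n_neg, replace=False)
        signs[neg_at] = -1.0
        w[idx] = mags * signs
        return w

    return PhantomAtlas(grid_shape, region_labels, _signed_weights(bmi_idx),
                        _signed_weights(dis_idx), overlap_fraction, seed)


# --------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortConfig:
    """Study conditions for a phantom cohort.

    Effect sizes are in GMV units (baseline ~0.5): ``beta_bmi`` per kg/m² of
    BMI deviation, ``beta_disease`` per group indicator, ``clinical_coupling``
    per SD of the clinical latent factor.  ``gap_shift`` gives each group's
    mean latent gap propensity in kg/m² (positive: the brain looks like a
    higher-BMI brain than measured).
    """

    group_sizes: Mapping[str, int] = field(default_factory=lambda: {"HC": 600})
    n_sites: int = 4
    age_range: tuple[float, float] = (15.0, 75.0)
    bmi_range: tuple[float, float] = (18.5, 35.0)
    bmi_mean: float = 24.5
    bmi_sd: float = 3.5
    age_bmi_corr: float = 0.25
    baseline: float = 0.5
    age_slope_mean: float = -0.0015  # GMV per year, mild global atrophy
    age_slope_sd: float = 0.0005
    sex_effect_sd: float = 0.005
    site_offset_sd: float = 0.02
    beta_bmi: float = 0.005
    beta_disease: Mapping[str, float] = field(
        default_factory=lambda: {"SCZ": 0.020, "CHR": 0.008, "ROD": 0.005})
    gap_shift: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "SCZ": 1.05, "CHR": 0.51, "ROD": -0.82})
    gap_sd: float = 1.5
    clinical_coupling: float = 0.006
    noise_sd: float = 0.04
    noise_smooth_fwhm: float = 0.0
    female_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"HC": 0.5, "SCZ": 0.23, "CHR": 0.48, "ROD": 0.48})
    # lifestyle covariates (Bernoulli rates), used by weight-gain classifiers
    exercise_rate: float = 0.5
    somatic_rate: float = 0.3
    tobacco_rate: float = 0.4
    # patient age distributions (mean, sd); HC ages are uniform in age_range
    age_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"SCZ": (31.0, 10.0), "CHR": (24.0, 5.0),
                                 "ROD": (26.0, 6.0)})


#: clinical variable -> (intercept, scale, loading on the shared latent factor)
CLINICAL_SPEC: dict[str, tuple[float, float, float]] = {
    "panss_total": (52.0, 18.0, 0.6),
    "age_of_onset": (24.0, 5.0, 0.5),
    "illness_duration": (3.0, 2.0, 0.5),
    "hospitalizations": (1.5, 1.5, 0.6),
}


@dataclass
class TruthRecord:
    """Ground truth: every systematic component of the voxel matrix."""

    seed: int
    propensity: np.ndarray  # (n,) latent gap, kg/m²
    clinical_latent: np.ndarray  # (n,)
    age_slopes: np.ndarray  # (V,)
    sex_effects: np.ndarray  # (V,)
    site_offsets: np.ndarray  # (n_sites,)
    clinical_loadings: dict[str, tuple[float, float, float]]
    beta_bmi: float
    beta_disease: dict[str, float]
    clinical_coupling: float
    baseline: float
    age_center: float
    bmi_center: float
    weight_gamma: tuple[float, float] | None = None


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=size)
    return mean + sd * stats.norm.ppf(u)


def simulate_cohort(atlas: PhantomAtlas, config: CohortConfig | None = None,
                    seed: int = 0):
    """Simulate (SubjectTable, GMVMatrix, TruthRecord) from an atlas.

    The voxel model for subject i, voxel v is additive::

        x_iv = baseline + slope_v (age_i - 45) + sexeff_v (sex_i - 0.5)
             + site_offset[site_i]
             + beta_bmi (BMI_i - bmi_mean + propensity_i) bmisig_v
             + beta_disease[group_i] dissig_v
             + coupling * latent_i * dissig_v[overlap voxels]
             + noise_iv

    so the latent gap propensity manifests exactly as extra apparent BMI on
    the BMI signature, and patient clinical scores share a latent factor with
    GMV in the BMI/disease overlap region.
    """
    cfg = config or CohortConfig()
    if cfg.noise_sd <= 0:
        # exact-limit tests use noise_sd ~ 0; forbid only negatives
        if cfg.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
    for k, v in cfg.group_sizes.items():
        if v < 0:
            raise ConfigError(f"negative group size for {k}")
    if not all(np.isfinite([cfg.beta_bmi, cfg.clinical_coupling])):
        raise ConfigError("effect sizes must be finite")

    rng = np.random.default_rng(seed)
    groups = [g for g, n in cfg.group_sizes.items() for _ in range(n)]
    n = len(groups)
    if n == 0:
        raise ConfigError("empty cohort")
    group_arr = np.asarray(groups)

    site = rng.integers(0, cfg.n_sites, size=n)
    female_p = np.array([cfg.female_fraction.get(g, 0.5) for g in groups])
    sex = (rng.uniform(size=n) < female_p).astype(int)  # 1 = female

    # age & BMI through a Gaussian copula so cor(age, BMI) ~ age_bmi_corr
    rho = cfg.age_bmi_corr
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    u_age, u_bmi = stats.norm.cdf(z[:, 0]), stats.norm.cdf(z[:, 1])
    lo_a, hi_a = cfg.age_range
    age = np.empty(n)
    hc = group_arr == "HC"
    age[hc] = lo_a + (hi_a - lo_a) * u_age[hc]
    for g, (m, s) in cfg.age_params.items():
        sel = group_arr == g
        if sel.any():
            a, b = (lo_a - m) / s, (hi_a - m) / s
            ua = stats.norm.cdf(a) + u_age[sel] * (stats.norm.cdf(b) - stats.norm.cdf(a))
            age[sel] = m + s * stats.norm.ppf(ua)
    lo_b, hi_b = cfg.bmi_range
    a, b = (lo_b - cfg.bmi_mean) / cfg.bmi_sd, (hi_b - cfg.bmi_mean) / cfg.bmi_sd
    ub = stats.norm.cdf(a) + u_bmi * (stats.norm.cdf(b) - stats.norm.cdf(a))
    bmi = cfg.bmi_mean + cfg.bmi_sd * stats.norm.ppf(ub)

    propensity = np.array([cfg.gap_shift.get(g, 0.0) for g in groups]) \
        + rng.normal(0.0, cfg.gap_sd, size=n)
    latent = np.where(np.isin(group_arr, PATIENT_GROUPS),
                      rng.normal(size=n), 0.0)

    # clinical scores for patients from the shared latent factor
    clin = {name: np.full(n, np.nan) for name in CLINICAL_SPEC}
    pat = np.isin(group_arr, PATIENT_GROUPS)
    for name, (icpt, scale, load) in CLINICAL_SPEC.items():
        eps = rng.normal(size=n)
        val = icpt + scale * (load * latent + np.sqrt(1 - load ** 2) * eps)
        if name == "age_of_onset":
            val = np.minimum(val, age - 0.5)
        if name in ("illness_duration", "hospitalizations"):
            val = np.maximum(val, 0.0)
        if name == "hospitalizations":
            val = np.round(val)
        clin[name][pat] = val[pat]

    # voxel-level parameters
    V = atlas.n_voxels
    age_slopes = rng.normal(cfg.age_slope_mean, cfg.age_slope_sd, size=V)
    sex_effects = rng.normal(0.0, cfg.sex_effect_sd, size=V)
    site_offsets = rng.normal(0.0, cfg.site_offset_sd, size=cfg.n_sites)

    age_center = 0.5 * (lo_a + hi_a)
    bmi_center = cfg.bmi_mean
    dis_eff = np.array([cfg.beta_disease.get(g, 0.0) if g in PATIENT_GROUPS else 0.0
                        for g in groups])
    overlap_sig = np.where(atlas.overlap_mask, atlas.disease_signature, 0.0)

    X = np.empty((n, V))
    X[:] = cfg.baseline
    X += np.outer(age - age_center, age_slopes)
    X += np.outer(sex - 0.5, sex_effects)
    X += site_offsets[site][:, None]
    X += cfg.beta_bmi * np.outer(bmi - bmi_center + propensity, atlas.bmi_signature)
    X += np.outer(dis_eff, atlas.disease_signature)
    X += cfg.clinical_coupling * np.outer(latent, overlap_sig)

    noise = rng.normal(0.0, 1.0, size=(n, V)) * cfg.noise_sd
    if cfg.noise_smooth_fwhm > 0:
        sigma = cfg.noise_smooth_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        vols = noise.reshape((n, *atlas.grid_shape))
        noise = np.stack([ndimage.gaussian_filter(v, sigma) for v in vols]
                         ).reshape(n, V)
    X += noise

    height = np.where(sex == 1, rng.normal(165.0, 7.0, size=n),
                      rng.normal(178.0, 7.0, size=n))
    weight_t0 = bmi * (height / 100.0) ** 2
    exercise = (rng.uniform(size=n) < cfg.exercise_rate).astype(int)
    somatic = (rng.uniform(size=n) < cfg.somatic_rate).astype(int)
    tobacco = (rng.uniform(size=n) < cfg.tobacco_rate).astype(int)

    table = pd.DataFrame({
        "id": [f"S{i:05d}" for i in range(n)],
        "group": group_arr,
        "site": [f"site_{s}" for s in site],
        "sex": np.where(sex == 1, "F", "M"),
        "age": age,
        "bmi": bmi,
        "weight_t0": weight_t0,
        "exercise": exercise,
        "somatic_history": somatic,
        "tobacco": tobacco,
        **clin,
    })
    gmv = GMVMatrix(X, atlas.grid_shape, None, table["id"].to_numpy())
    truth = TruthRecord(
        seed=seed, propensity=propensity, clinical_latent=latent,
        age_slopes=age_slopes, sex_effects=sex_effects, site_offsets=site_offsets,
        clinical_loadings=dict(CLINICAL_SPEC), beta_bmi=cfg.beta_bmi,
        beta_disease=dict(cfg.beta_disease), clinical_coupling=cfg.clinical_coupling,
        baseline=cfg.baseline, age_center=age_center, bmi_center=bmi_center,
    )
    return table, gmv, truth


def reconstruct_systematic(atlas: PhantomAtlas, table: pd.DataFrame,
                           truth: TruthRecord, config: CohortConfig | None = None
                           ) -> np.ndarray:
    """Recompute the systematic (noise-free) voxel matrix from the truth."""
    cfg = config or CohortConfig()
    sex = (table["sex"].to_numpy() == "F").astype(int)
    site = np.asarray([int(s.split("_")[1]) for s in table["site"]])
    group = table["group"].to_numpy()
    dis_eff = np.array([truth.beta_disease.get(g, 0.0) if g in PATIENT_GROUPS else 0.0
                        for g in group])
    overlap_sig = np.where(atlas.overlap_mask, atlas.disease_signature, 0.0)
    X = np.full((len(table), atlas.n_voxels), truth.baseline)
    X += np.outer(table["age"].to_numpy() - truth.age_center, truth.age_slopes)
    X += np.outer(sex - 0.5, truth.sex_effects)
    X += truth.site_offsets[site][:, None]
    X += truth.beta_bmi * np.outer(
        table["bmi"].to_numpy() - truth.bmi_center + truth.propensity,
        atlas.bmi_signature)
    X += np.outer(dis_eff, atlas.disease_signature)
    X += truth.clinical_coupling * np.outer(truth.clinical_latent, overlap_sig)
    return X


# --------------------------------------------------------------------------
# longitudinal weights


def simulate_longitudinal(table: pd.DataFrame, truth: TruthRecord,
                          gamma: tuple[float, float] = (0.5, 1.0),
                          noise_sd: float = 3.0,
                          missing_rate: tuple[float, float] = (0.3, 0.5),
                          age_coef: float = -0.08,
                          group_offsets: Mapping[str, float] | None = None,
                          seed: int = 0) -> pd.DataFrame:
    """Add weight_t1 / weight_t2 follow-up columns.

    Weight change at horizon h is ``gamma[h] * propensity + age/group
    modifiers + N(0, noise_sd)``, with missing-at-random dropout.  The 2-year
    coupling is required to be at least the 1-year coupling, matching the
    stronger long-horizon association this design emulates.
    """
    if "weight_t0" not in table or table["weight_t0"].isna().any():
        raise ConfigError("weight_t0 must be present for all subjects")
    g1, g2 = gamma
    if not (abs(g2) >= abs(g1)):
        raise ConfigError("2-year coupling must be >= 1-year coupling in magnitude")
    for m in missing_rate:
        if not 0.0 <= m <= 1.0:
            raise ConfigError("missing rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    n = len(table)
    age = table["age"].to_numpy()
    offs = np.array([(group_offsets or {}).get(g, 0.0) for g in table["group"]])
    mod = age_coef * (age - float(np.mean(age))) + offs
    out = table.copy()
    for h, (g, miss) in enumerate(zip((g1, g2), missing_rate), start=1):
        dw = g * truth.propensity + mod + rng.normal(0.0, noise_sd, size=n)
        w = table["weight_t0"].to_numpy() + dw
        drop = rng.uniform(size=n) < miss
        w = np.where(drop, np.nan, w)
        out[f"weight_t{h}"] = w
    truth.weight_gamma = (g1, g2)
    return out
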