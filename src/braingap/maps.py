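"""Voxel-level model interpretation maps.

Two complementary reliability summaries are computed over the k*r
back-projected voxel weight vectors of a trained ensemble:

* the cross-validation ratio (CVR): mean weight divided by the standard
  error of the mean across ensemble members — a t-like magnitude score; and
* sign-based consistency: the fraction of members agreeing on the weight's
  sign, tested per voxel against chance with an exact two-sided binomial
  test and corrected across voxels with Benjamini-Hochberg FDR.

Binarized (q-thresholded) consistency masks from two predictors (e.g. BMI
and diagnosis) can then be intersected to locate brain regions predictive
of both phenotypes, with per-voxel sign concordance recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["VoxelStatMap", "OverlapMask", "cvr_map", "sign_consistency_map",
           "binarize_map", "overlap_masks"]

CVR_CAP = 1e6  # signed cap when the SE across members is exactly zero


@dataclass
class VoxelStatMap:
    """Per-voxel ensemble statistics (NaN where undefined/excluded)."""

    mean_weight: np.ndarray
    se_weight: np.ndarray | None = None
    cvr: np.ndarray | None = None
    cvr_capped: np.ndarray | None = None  # bool, SE == 0
    consistency: np.ndarray | None = None  # majority fraction in [0.5, 1]
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    # empirical-null standardization of the grand-mean weight map
    z_emp: np.ndarray | None = None
    p_emp: np.ndarray | None = None
    q_emp: np.ndarray | None = None
    grid_shape: tuple | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"voxel": np.arange(self.mean_weight.size),
                "mean_weight": self.mean_weight}
        for name in ("se_weight", "cvr", "consistency", "p", "q",
                     "z_emp", "p_emp", "q_emp"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)


def cvr_map(weights: np.ndarray, grid_shape=None) -> VoxelStatMap:
    """Cross-validation ratio: per-voxel mean weight / SE of the mean.

    ``weights`` is (n_members, n_voxels) with n_members >= 2.  A voxel with
    identical weights in every member (SE = 0) gets a signed capped CVR and
    is flagged.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need a (members, voxels) matrix with >= 2 members")
    m = W.shape[0]
    mean = W.mean(axis=0)
    se = W.std(axis=0, ddof=1) / np.sqrt(m)
    capped = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cvr = mean / se
    cvr[capped] = np.sign(mean[capped]) * CVR_CAP
    if capped.any():
        log.info("%d voxel(s) with zero SE: CVR capped", int(capped.sum()))
    return VoxelStatMap(mean_weight=mean, se_weight=se, cvr=cvr,
                        cvr_capped=capped, grid_shape=grid_shape)


def sign_consistency_map(weights: np.ndarray, grid_shape=None) -> VoxelStatMap:
    """Sign-based consistency with exact binomial test and BH FDR.

    Exact-zero weights are excluded from a voxel's sign count; voxels that
    are zero in every member are excluded entirely (NaN).

    The binomial test treats ensemble members as independent sign draws.
    CV members share most of their training subjects, so at a truly
    signal-free voxel the members inherit the *same* cohort-level chance
    correlation and agree in sign far more often than the binomial null
    allows; the binomial p/q fields are therefore descriptive reliability
    summaries, not calibrated voxel-level inference.  Calibrated inference
    is provided by the ``z_emp``/``p_emp``/``q_emp`` fields: the grand-mean
    weight map standardized against an empirical null (median and MAD
    across in-mask voxels, assuming most voxels carry no signal), with BH
    FDR across voxels.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] < 8:
        raise ValueError("need >= 8 ensemble members for a meaningful test")
    n_pos = (W > 0).sum(axis=0)
    n_neg = (W < 0).sum(axis=0)
    m = n_pos + n_neg  # zeros excluded
    tested = m > 0
    if not tested.all():
        log.info("%d all-zero voxel(s) excluded from sign consistency",
                 int((~tested).sum()))
    V = W.shape[1]
    consistency = np.full(V, np.nan)
    p = np.full(V, np.nan)
    kmaj = np.maximum(n_pos, n_neg)
    consistency[tested] = kmaj[tested] / m[tested]
    # two-sided exact binomial against 0.5: P(|X - m/2| >= |k - m/2|)
    kmin = np.minimum(n_pos, n_neg)
    p[tested] = np.minimum(1.0, 2.0 * stats.binom.cdf(kmin[tested], m[tested], 0.5))
    q = np.full(V, np.nan)
    q[tested] = stats.false_discovery_control(p[tested], method="bh")
    mean = W.mean(axis=0)
    # empirical-null calibration of the grand-mean weight map
    med = float(np.median(mean[tested])) if tested.any() else 0.0
    mad = float(np.median(np.abs(mean[tested] - med))) * 1.4826 if tested.any() else 0.0
    z_emp = np.full(V, np.nan)
    p_emp = np.full(V, np.nan)
    q_emp = np.full(V, np.nan)
    if mad > 0:
        z_emp[tested] = (mean[tested] - med) / mad
        p_emp[tested] = 2.0 * stats.norm.sf(np.abs(z_emp[tested]))
        q_emp[tested] = stats.false_discovery_control(p_emp[tested], method="bh")
    return VoxelStatMap(mean_weight=mean, consistency=consistency, p=p, q=q,
                        z_emp=z_emp, p_emp=p_emp, q_emp=q_emp,
                        grid_shape=grid_shape)


def binarize_map(stat_map: VoxelStatMap, q_threshold: float = 0.05,
                 method: str = "calibrated") -> np.ndarray:
    """Boolean mask of voxels with FDR q <= threshold.

    ``method="calibrated"`` (default) thresholds the empirical-null q-values
    when the map provides them, falling back to the binomial q otherwise;
    ``method="binomial"`` forces the raw binomial-consistency q.
    """
    q = stat_map.q
    if method == "calibrated" and stat_map.q_emp is not None:
        q = stat_map.q_emp
    if q is None:
        raise ValueError("q-values not computed for this map")
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(q, nan=np.inf) <= q_threshold


@dataclass
class OverlapMask:
    """Intersection of two binarized maps with sign-concordance bookkeeping."""

    mask: np.ndarray  # bool per voxel
    sign_concordant: np.ndarray  # bool per voxel (valid inside mask)
    q_threshold_a: float
    q_threshold_b: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def overlap_masks(mask_a: np.ndarray, mask_b: np.ndarray,
                  map_a: VoxelStatMap | None = None,
                  map_b: VoxelStatMap | None = None,
                  q_a: float = 0.05, q_b: float = 0.05) -> OverlapMask:
    """Logical AND of two voxel masks on identical grids; overlap is
    sign-agnostic but per-voxel concordance of the parent mean-weight signs
    is recorded."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("grid mismatch between the two masks")
    both = mask_a & mask_b
    if map_a is not None and map_b is not None:
        conc = np.sign(map_a.mean_weight) == np.sign(map_b.mean_weight)
    else:
        conc = np.zeros_like(both)
    return OverlapMask(mask=both, sign_concordant=conc & both,
                       q_threshold_a=q_a, q_threshold_b=q_b)
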