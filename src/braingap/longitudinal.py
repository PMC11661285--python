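"""BMI gap versus future weight change.

Three analyses: (i) weight-change computation at 1- and 2-year follow-up
(absolute and percent of baseline weight); (ii) correlation scans between
the corrected BMI gap and weight change across subgroup filters — minimum
weight-gain thresholds (all / >=3% / >=5% / >=7%), age windows, sex and
clinical group; and (iii) individual-level weight-gain classification
(linear SVC under the nested-CV engine on a small tabular feature set, with
in-fold standardization and median imputation only) with an ablation
comparison quantifying the contribution of the BMI gap feature via a paired
sign-flip permutation test on per-subject correctness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GMVMatrix
from .nestedcv import (CVAssignment, evaluate_classification, make_cv,
                       train_nested)
from .preprocess import ChainConfig

log = logging.getLogger(__name__)

__all__ = ["compute_weight_change", "subgroup_correlation_scan",
           "weight_gain_labels", "predict_weight_gain", "ablation_compare",
           "ClassifierReport", "TABULAR_CHAIN", "DEFAULT_FEATURES"]

HORIZONS = (1, 2)

#: preprocessing for tabular classifiers: no smoothing/residualization/site
#: correction/PCA — in-fold median imputation and z-scoring only
TABULAR_CHAIN = ChainConfig(smooth_fwhm=0.0, residualize_age=False,
                            site_correction=False, pca_variance=None,
                            scaling="zscore", impute=True)

DEFAULT_FEATURES = ("bmigap", "age", "sex", "group_rod", "exercise",
                    "somatic_history", "tobacco")


def compute_weight_change(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject weight change and percent change at each horizon.

    Missing follow-up weights propagate to NA (the subject is retained);
    rows with non-positive baseline weight are flagged invalid.
    """
    if "weight_t0" not in table:
        raise KeyError("weight_t0 column required")
    out = table[["id", "weight_t0"]].copy()
    w0 = pd.to_numeric(table["weight_t0"], errors="coerce")
    invalid = (w0 <= 0) | w0.isna()
    if invalid.any():
        log.warning("%d row(s) with missing/non-positive baseline weight",
                    int(invalid.sum()))
    out["valid_baseline"] = ~invalid
    for h in HORIZONS:
        col = f"weight_t{h}"
        wh = pd.to_numeric(table[col], errors="coerce") if col in table \
            else pd.Series(np.nan, index=table.index)
        out[col] = wh
        dw = wh - w0
        out[f"dw{h}"] = dw
        out[f"pct{h}"] = np.where(invalid, np.nan, 100.0 * dw / w0)
    return out


def _scan_cell(gap: np.ndarray, dw: np.ndarray, min_n: int = 5) -> dict:
    ok = ~np.isnan(gap) & ~np.isnan(dw)
    n = int(ok.sum())
    if n < min_n or np.std(gap[ok]) == 0 or np.std(dw[ok]) == 0:
        return {"n": n, "r": np.nan, "p": np.nan}
    r, p = stats.pearsonr(gap[ok], dw[ok])
    return {"n": n, "r": float(r), "p": float(p)}


def subgroup_correlation_scan(gap_table: pd.DataFrame, wc: pd.DataFrame,
                              thresholds: Sequence[float] = (0.0, 3.0, 5.0, 7.0),
                              age_windows: Sequence[tuple] = ((15, 100),),
                              by_sex: bool = False, by_group: bool = False,
                              subjects: pd.DataFrame | None = None,
                              min_n: int = 5) -> pd.DataFrame:
    """Pearson correlation between corrected gap and weight change per
    (horizon x threshold x age window [x sex] [x group]) cell.

    ``thresholds`` are minimum percent weight gain filters (0 keeps
    everyone); cells smaller than ``min_n`` are reported with r = NA.
    """
    df = gap_table.merge(wc, on="id", how="inner")
    if subjects is not None:
        cols = [c for c in ("id", "age", "sex", "group") if c in subjects]
        df = df.merge(subjects[cols], on="id", how="left",
                      suffixes=("", "_subj"))
    gap = df["gap_corrected"].to_numpy(dtype=float)
    rows = []
    sexes = sorted(df["sex"].dropna().unique()) if by_sex and "sex" in df else [None]
    groups = sorted(df["group"].dropna().unique()) if by_group and "group" in df else [None]
    for h in HORIZONS:
        dw = df[f"dw{h}"].to_numpy(dtype=float)
        pct = df[f"pct{h}"].to_numpy(dtype=float)
        for thr in thresholds:
            base = np.ones(len(df), dtype=bool) if thr == 0 else \
                np.nan_to_num(pct, nan=-np.inf) >= thr
            for lo, hi in age_windows:
                agesel = np.ones(len(df), dtype=bool)
                if "age" in df:
                    age = df["age"].to_numpy(dtype=float)
                    agesel = (age >= lo) & (age <= hi)
                for s in sexes:
                    ssel = np.ones(len(df), dtype=bool) if s is None else \
                        (df["sex"] == s).to_numpy()
                    for g in groups:
                        gsel = np.ones(len(df), dtype=bool) if g is None else \
                            (df["group"] == g).to_numpy()
                        sel = base & agesel & ssel & gsel
                        cell = _scan_cell(gap[sel], dw[sel], min_n)
                        rows.append({"horizon": f"T{h}",
                                     "threshold_pct": thr,
                                     "age_lo": lo, "age_hi": hi,
                                     "sex": s or "all", "group": g or "all",
                                     **cell})
    return pd.DataFrame(rows)


def weight_gain_labels(wc: pd.DataFrame, threshold_pct: float,
                       horizon: int) -> pd.Series:
    """Binary gain/no-gain labels at a horizon: 1 iff percent change >=
    threshold (inclusive); subjects with missing follow-up are dropped."""
    pct = wc[f"pct{horizon}"]
    ok = pct.notna() & wc["valid_baseline"]
    labels = (pct[ok] >= threshold_pct).astype(int)
    labels.index = wc.loc[ok, "id"]
    return labels


@dataclass
class ClassifierReport:
    bac: float
    sensitivity: float
    specificity: float
    n: int
    feature_names: list
    feature_weights: np.ndarray  # mean back-projected weight per feature
    prediction_table: pd.DataFrame
    cv: CVAssignment
    permutation_p: float | None = None


def predict_weight_gain(features: pd.DataFrame, labels: pd.Series,
                        cv: CVAssignment | None = None, k: int = 5, r: int = 5,
                        grid: dict | None = None, seed: int = 0
                        ) -> ClassifierReport:
    """Weight-gain classifier on a tabular feature set.

    ``features`` is indexed by subject id with numeric columns (e.g. BMI
    gap, age, sex, group indicator, exercise, somatic history, tobacco);
    rows are aligned to ``labels``.  Uses the nested-CV SVC engine with
    in-fold median imputation and z-scoring (no imaging preprocessing).
    """
    X = features.loc[labels.index]
    y = labels.to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    gmv = GMVMatrix(X.to_numpy(dtype=float), None, None,
                    np.asarray(labels.index))
    if cv is None:
        cv = make_cv(len(y), k=k, r=r, seed=seed, stratify=y)
    ens, pred = train_nested(gmv, None, y, cv, task="svc", grid=grid,
                             chain_config=TABULAR_CHAIN, seed=seed)
    metrics = evaluate_classification(pred, positive=1)
    W = ens.voxel_weight_matrix()  # members x features (identity "PCA")
    return ClassifierReport(
        bac=metrics["BAC"], sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"], n=len(y),
        feature_names=list(X.columns), feature_weights=W.mean(axis=0),
        prediction_table=pred, cv=cv)


def ablation_compare(report_with: ClassifierReport,
                     report_without: ClassifierReport,
                     n_perm: int = 10000, seed: int = 0) -> dict:
    """Paired sign-flip permutation test on per-subject correctness.

    Both models must have been evaluated on the same subjects under the
    same CV assignment.  The statistic is |mean difference of per-subject
    ensemble correctness|; signs of the paired differences are flipped
    uniformly at random.  Also reports the balanced-accuracy difference.
    """
    a, b = report_with.prediction_table, report_without.prediction_table
    if not np.array_equal(a["id"].to_numpy(), b["id"].to_numpy()) or \
            not np.array_equal(a["y_true"].to_numpy(), b["y_true"].to_numpy()):
        raise ValueError("models were not evaluated on identical subjects")
    if not np.array_equal(report_with.cv.outer, report_without.cv.outer):
        raise ValueError("CV assignment mismatch between the two models")
    ca = (a["ensemble"].to_numpy() == a["y_true"].to_numpy()).astype(float)
    cb = (b["ensemble"].to_numpy() == b["y_true"].to_numpy()).astype(float)
    d = ca - cb
    obs = abs(float(d.mean()))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        flips = rng.integers(0, 2, size=d.size) * 2 - 1
        if abs(float((d * flips).mean())) >= obs - 1e-15:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return {"p": p, "delta_accuracy": float(d.mean()),
            "delta_bac": report_with.bac - report_without.bac,
            "n_perm": n_perm}
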