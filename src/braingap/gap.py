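"""BMI-gap computation and regression-to-the-mean bias correction.

The raw gap (predicted minus measured BMI) of any regression-based
phenotype predictor is negatively correlated with the measured phenotype:
low-BMI subjects are over-estimated and high-BMI subjects under-estimated.
The correction fits ``gap_raw ~ a + b * BMI_measured`` by ordinary least
squares in a reference cohort (the discovery sample, whose out-of-fold
predictions are unbiased) and subtracts the fitted line everywhere, so the
corrected gap has mean zero and zero correlation with measured BMI in the
reference cohort while *preserving* genuine group-level shifts in any
target cohort the frozen coefficients are transferred to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["GapCorrection", "compute_gap", "fit_gap_correction",
           "apply_gap_correction", "make_gap_table", "summarize_gap_by_group"]


@dataclass(frozen=True)
class GapCorrection:
    """Frozen linear bias-correction coefficients (gap = a + b * BMI)."""

    intercept: float  # kg/m²
    slope: float  # dimensionless
    cohort_id: str
    n: int


def compute_gap(predicted, measured) -> np.ndarray:
    """Raw gap: predicted minus measured phenotype, elementwise."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ValueError("predicted and measured must be paired")
    return predicted - measured


def fit_gap_correction(gap_raw, measured, cohort_id: str = "discovery"
                       ) -> GapCorrection:
    """OLS fit of raw gap on measured BMI in the reference cohort."""
    gap_raw = np.asarray(gap_raw, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if gap_raw.size < 3:
        raise ValueError("need at least 3 subjects to fit the correction")
    if np.var(measured) == 0:
        raise ValueError("zero BMI variance: correction not identifiable")
    b, a = np.polyfit(measured, gap_raw, deg=1)
    return GapCorrection(intercept=float(a), slope=float(b),
                         cohort_id=cohort_id, n=int(gap_raw.size))


def apply_gap_correction(correction: GapCorrection, gap_raw, measured
                         ) -> np.ndarray:
    """Subtract the frozen fitted line; identical arithmetic for reference
    and target cohorts (never refit on the target)."""
    gap_raw = np.asarray(gap_raw, dtype=float)
    measured = np.asarray(measured, dtype=float)
    return gap_raw - (correction.intercept + correction.slope * measured)


def make_gap_table(ids, group, measured, predicted,
                   correction: GapCorrection) -> pd.DataFrame:
    """Assemble the per-subject gap table (raw and corrected)."""
    raw = compute_gap(predicted, measured)
    return pd.DataFrame({
        "id": np.asarray(ids),
        "group": np.asarray(group),
        "bmi_measured": np.asarray(measured, dtype=float),
        "bmi_predicted": np.asarray(predicted, dtype=float),
        "gap_raw": raw,
        "gap_corrected": apply_gap_correction(correction, raw, measured),
    })


def summarize_gap_by_group(gap_table: pd.DataFrame) -> pd.DataFrame:
    """Per-group n, mean and SD of raw and corrected gap (SD is NA for n=1)."""
    rows = []
    for g, sub in gap_table.groupby("group", sort=False):
        if len(sub) == 0:
            log.warning("empty group %r omitted from summary", g)
            continue
        rows.append({
            "group": g, "n": len(sub),
            "gap_raw_mean": float(sub["gap_raw"].mean()),
            "gap_raw_sd": float(sub["gap_raw"].std(ddof=1)) if len(sub) > 1 else np.nan,
            "gap_corrected_mean": float(sub["gap_corrected"].mean()),
            "gap_corrected_sd": float(sub["gap_corrected"].std(ddof=1))
            if len(sub) > 1 else np.nan,
        })
    return pd.DataFrame(rows)
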