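"""Inclusion filtering and discovery-sample construction.

A BMI predictor generalizes best when trained on a sample that covers the
whole BMI range evenly, so the discovery sample is drawn by stratifying
candidates into fixed-width BMI bins (18.5-35 kg/m² at 0.5 kg/m² per bin
gives 33 bins) and filling each bin to a common quota.  Because age and BMI
are naturally correlated, subjects within each bin are chosen by greedy
quantile matching of their ages against the pooled age distribution, which
decouples age from BMI across bins.  Everyone not selected stays in the
validation sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["BinSpec", "SplitAssignment", "apply_inclusion", "bin_bmi",
           "sample_uniform_with_matching"]


@dataclass(frozen=True)
class BinSpec:
    """Half-open BMI bins [lo + k*w, lo + (k+1)*w), last bin closed at hi."""

    lo: float = 18.5
    hi: float = 35.0
    width: float = 0.5

    @property
    def n_bins(self) -> int:
        return int(round((self.hi - self.lo) / self.width))

    def edges(self) -> np.ndarray:
        return self.lo + self.width * np.arange(self.n_bins + 1)


@dataclass
class SplitAssignment:
    """Discovery/validation partition with per-bin diagnostics."""

    table: pd.DataFrame  # columns: id, partition, bin, reason
    bin_counts: pd.DataFrame  # columns: bin, n_candidates, n_discovery, age_mean, age_sd
    seed: int

    def ids(self, partition: str) -> np.ndarray:
        return self.table.loc[self.table["partition"] == partition, "id"].to_numpy()


def apply_inclusion(table: pd.DataFrame, age_range=(15.0, 75.0),
                    bmi_range=(18.5, 35.0)):
    """Filter to the analysis age/BMI window (closed bounds on both ends).

    Returns ``(included, exclusions)``; exclusions carry a per-subject
    reason (``age``, ``bmi`` or ``missing``) rather than raising.
    """
    if "age" not in table or "bmi" not in table:
        raise KeyError("table must have 'age' and 'bmi' columns")
    age = pd.to_numeric(table["age"], errors="coerce")
    bmi = pd.to_numeric(table["bmi"], errors="coerce")
    reason = np.full(len(table), "", dtype=object)
    reason[(age.isna() | bmi.isna()).to_numpy()] = "missing"
    bad_age = ((age < age_range[0]) | (age > age_range[1])).to_numpy() & (reason == "")
    reason[bad_age] = "age"
    bad_bmi = ((bmi < bmi_range[0]) | (bmi > bmi_range[1])).to_numpy() & (reason == "")
    reason[bad_bmi] = "bmi"
    keep = reason == ""
    excl = table.loc[~keep, ["id"]].copy() if "id" in table else pd.DataFrame(
        index=table.index[~keep])
    excl["reason"] = reason[~keep]
    return table.loc[keep].reset_index(drop=True), excl.reset_index(drop=True)


def bin_bmi(bmi, spec: BinSpec = BinSpec()) -> np.ndarray:
    """Bin index per value; values must lie within [lo, hi] (inclusion first)."""
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi < spec.lo) or np.any(bmi > spec.hi):
        raise ValueError(
            f"BMI values outside [{spec.lo}, {spec.hi}]; run inclusion first")
    idx = np.floor((bmi - spec.lo) / spec.width).astype(int)
    return np.minimum(idx, spec.n_bins - 1)  # hi falls into the last, closed bin


def _quotas(counts: np.ndarray, total_n: int) -> np.ndarray:
    """Per-bin discovery quotas: ceil(total/n_bins) each, greedily trimmed to
    total_n, with shortfalls of under-supplied bins pushed to the nearest
    bins that still have spare candidates."""
    n_bins = counts.size
    target = np.full(n_bins, int(np.ceil(total_n / n_bins)))
    # trim the surplus round-robin from the bins with the largest quota
    while target.sum() > total_n:
        order = np.lexsort((np.arange(n_bins), -target))
        target[order[0]] -= 1
    # redistribute shortfalls to neighbouring bins
    quota = np.minimum(target, counts)
    deficit = int(target.sum() - quota.sum())
    if deficit:
        log.warning("bins short of candidates; redistributing %d slots", deficit)
    while deficit > 0:
        spare = counts - quota
        if spare.sum() == 0:
            break
        short = np.flatnonzero(target > quota)
        # distance from any short bin, preferring nearby bins
        dist = np.min(np.abs(np.arange(n_bins)[:, None] - short[None, :]), axis=1)
        dist[spare == 0] = n_bins + 1
        k = int(np.argmin(dist))
        quota[k] += 1
        deficit -= 1
    return quota


def sample_uniform_with_matching(table: pd.DataFrame, spec: BinSpec,
                                 total_n: int, match_on: str = "age",
                                 seed: int = 0) -> SplitAssignment:
    """Select a discovery sample approximately uniform in BMI, with the
    matching covariate's within-bin distribution greedily matched to the
    pooled distribution; the remainder becomes the validation sample."""
    if total_n > len(table):
        raise ValueError("total_n exceeds table size")
    rng = np.random.default_rng(seed)
    bins = bin_bmi(table["bmi"].to_numpy(), spec)
    counts = np.bincount(bins, minlength=spec.n_bins)
    quota = _quotas(counts, total_n)

    cov = table[match_on].to_numpy(dtype=float)
    partition = np.full(len(table), "validation", dtype=object)
    for b in range(spec.n_bins):
        m = int(quota[b])
        if m == 0:
            continue
        cand = np.flatnonzero(bins == b)
        cand = cand[rng.permutation(cand.size)]  # seeded tie-breaking order
        # greedy quantile matching against the pooled covariate distribution
        targets = np.quantile(cov, (np.arange(m) + 0.5) / m)
        chosen: list[int] = []
        avail = list(cand)
        for t in targets:
            j = int(np.argmin(np.abs(cov[avail] - t)))
            chosen.append(avail.pop(j))
        partition[chosen] = "discovery"

    out = pd.DataFrame({
        "id": table["id"].to_numpy() if "id" in table else np.arange(len(table)),
        "partition": partition,
        "bin": bins,
        "reason": "",
    })
    disc = out["partition"] == "discovery"
    diag = []
    for b in range(spec.n_bins):
        sel = disc & (out["bin"] == b)
        ages = cov[sel.to_numpy()]
        diag.append({"bin": b, "n_candidates": int(counts[b]),
                     "n_discovery": int(sel.sum()),
                     f"{match_on}_mean": float(np.mean(ages)) if ages.size else np.nan,
                     f"{match_on}_sd": float(np.std(ages, ddof=1)) if ages.size > 1 else np.nan})
    return SplitAssignment(out, pd.DataFrame(diag), seed)
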