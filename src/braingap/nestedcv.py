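"""Repeated nested cross-validation for linear SVR (BMI) and SVC (diagnosis).

The engine mirrors the discovery design of brain-phenotype prediction
studies: an outer cycle of k folds repeated r times yields k*r ensemble
members; inside each outer training partition an inner repeated CV selects
the hyperparameters (epsilon-insensitive linear SVR minimizing inner
out-of-fold MAE, or a linear SVC with inverse-frequency class weights
maximizing inner balanced accuracy); the preprocessing chain and model are
then refit on the full outer training partition and predictions are recorded
for the outer test fold only.  Out-of-fold predictions are averaged across
repetitions into the ensemble prediction; classifier decision scores are
averaged the same way (the "disease expression" score).

Because the preprocessing chain never sees labels, all chains and feature
matrices are computed once per CV assignment (:func:`build_feature_cache`)
and re-used across the hyperparameter grid and across label permutations,
which makes the permutation significance test affordable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC, LinearSVR

from .io import GMVMatrix
from .preprocess import ChainConfig, PreprocChain, backproject_weights, fit_chain, smooth_gmv

log = logging.getLogger(__name__)

__all__ = [
    "CVAssignment", "make_cv", "FeatureCache", "build_feature_cache",
    "TrainedEnsemble", "MemberModel", "train_nested", "apply_ensemble",
    "evaluate_regression", "evaluate_classification",
    "permutation_significance", "PermutationResult", "default_grid",
]


# --------------------------------------------------------------------------
# CV assignments


@dataclass
class CVAssignment:
    """Outer fold ids per subject per repetition (plus inner CV settings)."""

    n: int
    k: int
    r: int
    seed: int
    outer: np.ndarray  # (r, n) fold id in [0, k)
    inner_k: int = 5
    inner_r: int = 5

    @property
    def n_members(self) -> int:
        return self.k * self.r


def _fold_ids(n: int, k: int, rng: np.random.Generator,
              stratify: np.ndarray | None) -> np.ndarray:
    ids = np.empty(n, dtype=int)
    if stratify is None:
        perm = rng.permutation(n)
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        ids[perm] = np.repeat(np.arange(k), sizes)
    else:
        stratify = np.asarray(stratify)
        start = 0
        for s in np.unique(stratify):
            idx = np.flatnonzero(stratify == s)
            if idx.size < k:
                log.warning("stratum %r smaller than k=%d; distributed round-robin",
                            s, k)
            idx = idx[rng.permutation(idx.size)]
            # rotate the starting fold across strata so small strata spread out
            ids[idx] = (np.arange(idx.size) + start) % k
            start += idx.size
    return ids


def make_cv(n: int, k: int = 5, r: int = 5, seed: int = 0,
            stratify=None, inner_k: int = 5, inner_r: int = 5) -> CVAssignment:
    """Deterministic repeated k-fold assignment (optionally stratified)."""
    if n < k:
        raise ValueError("need at least k subjects")
    rng = np.random.default_rng(seed)
    outer = np.stack([_fold_ids(n, k, rng, stratify) for _ in range(r)])
    return CVAssignment(n=n, k=k, r=r, seed=seed, outer=outer,
                        inner_k=inner_k, inner_r=inner_r)


# --------------------------------------------------------------------------
# label-independent feature cache


@dataclass
class _Member:
    rep: int
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    chain: PreprocChain
    F_train: np.ndarray
    F_test: np.ndarray
    # inner folds: (train_rel, test_rel, F_inner_train, F_inner_test)
    inner: list = field(default_factory=list)


@dataclass
class FeatureCache:
    cv: CVAssignment
    chain_config: ChainConfig
    members: list


def build_feature_cache(gmv: GMVMatrix, covariates: pd.DataFrame | None,
                        cv: CVAssignment, chain_config: ChainConfig | None = None,
                        with_inner: bool = True) -> FeatureCache:
    """Fit all outer (and inner) preprocessing chains and transform features.

    Smoothing has no trainable parameters and acts on each subject
    independently, so the whole matrix is smoothed once up front; each
    fitted chain still records the kernel width for application to new data.
    """
    cfg = chain_config or ChainConfig()
    work = smooth_gmv(gmv, cfg.smooth_fwhm) if cfg.smooth_fwhm > 0 else gmv
    fit_cfg = replace(cfg, smooth_fwhm=0.0)

    members: list[_Member] = []
    for rep in range(cv.r):
        folds = cv.outer[rep]
        for fold in range(cv.k):
            test_idx = np.flatnonzero(folds == fold)
            train_idx = np.flatnonzero(folds != fold)
            cov_tr = None if covariates is None else covariates.iloc[train_idx]
            chain = fit_chain(work.select(train_idx), cov_tr, fit_cfg)
            F_train = chain.transform(work.select(train_idx), cov_tr)
            cov_te = None if covariates is None else covariates.iloc[test_idx]
            F_test = chain.transform(work.select(test_idx), cov_te)
            # record the true kernel width so application to raw data smooths
            chain.config = replace(cfg)
            member = _Member(rep, fold, train_idx, test_idx, chain, F_train, F_test)
            if with_inner:
                iseed = int(np.random.SeedSequence(
                    (cv.seed, rep, fold)).generate_state(1)[0] % (2 ** 31))
                icv = make_cv(train_idx.size, cv.inner_k, cv.inner_r, seed=iseed,
                              inner_k=1, inner_r=1)
                for irep in range(icv.r):
                    ifolds = icv.outer[irep]
                    for ifold in range(icv.k):
                        te_rel = np.flatnonzero(ifolds == ifold)
                        tr_rel = np.flatnonzero(ifolds != ifold)
                        abs_tr = train_idx[tr_rel]
                        abs_te = train_idx[te_rel]
                        cov_itr = None if covariates is None else covariates.iloc[abs_tr]
                        ichain = fit_chain(work.select(abs_tr), cov_itr, fit_cfg)
                        Fi_tr = ichain.transform(work.select(abs_tr), cov_itr)
                        cov_ite = None if covariates is None else covariates.iloc[abs_te]
                        Fi_te = ichain.transform(work.select(abs_te), cov_ite)
                        member.inner.append((tr_rel, te_rel, Fi_tr, Fi_te))
            members.append(member)
    return FeatureCache(cv=cv, chain_config=cfg, members=members)


# --------------------------------------------------------------------------
# models


def default_grid(task: str) -> dict:
    """Default hyperparameter grid: geometric C ladder; for regression the
    epsilon tube is set as a fraction of the training-label SD."""
    grid = {"C": list(2.0 ** np.arange(-6, 5))}
    if task == "svr":
        grid["epsilon_frac"] = [0.05, 0.1, 0.2]
    return grid


def _expand_settings(grid: dict, task: str, y_sd: float):
    Cs = sorted(grid.get("C", [1.0]))
    if task == "svr":
        eps = sorted(grid.get("epsilon_frac", [0.1]))
        return [(float(C), float(e * y_sd)) for C in Cs for e in eps]
    return [(float(C), None) for C in Cs]


def _fit_model(task: str, F: np.ndarray, y: np.ndarray, C: float,
               epsilon: float | None, seed: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if task == "svr":
            m = LinearSVR(C=C, epsilon=epsilon, loss="epsilon_insensitive",
                          dual=True, max_iter=20000, tol=1e-4,
                          random_state=seed)
            # centre the target: liblinear regularizes the bias term, so
            # fitting raw BMI-scale labels converges slowly and biases the
            # intercept; the offset is folded back in afterwards
            y = np.asarray(y, dtype=float)
            y_off = float(y.mean())
            m.fit(F, y - y_off)
            m.intercept_ = m.intercept_ + y_off
            return m
        elif task == "svc":
            m = LinearSVC(C=C, loss="hinge", dual=True,
                          class_weight="balanced", max_iter=20000, tol=1e-4,
                          random_state=seed)
        else:
            raise ValueError(f"unknown task {task!r}")
        m.fit(F, y)
    return m


def _bac(y_true, y_pred, classes) -> float:
    sens = np.mean(y_pred[y_true == classes[1]] == classes[1]) \
        if np.any(y_true == classes[1]) else np.nan
    spec = np.mean(y_pred[y_true == classes[0]] == classes[0]) \
        if np.any(y_true == classes[0]) else np.nan
    return float(np.nanmean([sens, spec]))


# --------------------------------------------------------------------------
# training


@dataclass
class MemberModel:
    rep: int
    fold: int
    chain: PreprocChain
    params: dict
    coef: np.ndarray
    intercept: float
    voxel_weights: np.ndarray
    voxel_const: float


@dataclass
class TrainedEnsemble:
    task: str
    cv: CVAssignment
    members: list
    classes: np.ndarray | None = None
    grid: dict | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    def voxel_weight_matrix(self) -> np.ndarray:
        """(n_members, n_voxels) back-projected weight matrix for mapping."""
        return np.stack([m.voxel_weights for m in self.members])


def _select_setting(member: _Member, y: np.ndarray, settings, task: str,
                    classes, seed: int):
    """Inner-CV score per setting; returns the winning (C, epsilon)."""
    if len(settings) == 1:
        return settings[0]
    y_tr = y[member.train_idx]
    best, best_score = None, None
    for C, eps in settings:
        errs: list[float] = []
        bacs: list[float] = []
        for tr_rel, te_rel, F_tr, F_te in member.inner:
            yi = y_tr[tr_rel]
            if task == "svc" and np.unique(yi).size < 2:
                continue
            if task == "svr" and np.ptp(yi) == 0:
                continue
            m = _fit_model(task, F_tr, yi, C, eps, seed)
            pred = m.predict(F_te)
            if task == "svr":
                errs.extend(np.abs(pred - y_tr[te_rel]))
            else:
                bacs.append(_bac(y_tr[te_rel], pred, classes))
        score = float(np.mean(errs)) if task == "svr" else -float(np.nanmean(bacs))
        # strict '<' with settings sorted ascending in (C, eps): ties break
        # toward the smaller regularization constant
        if best_score is None or score < best_score:
            best, best_score = (C, eps), score
    return best


def _train_on_cache(cache: FeatureCache, y: np.ndarray, task: str,
                    grid: dict | None, seed: int, want_members: bool):
    cv = cache.cv
    y = np.asarray(y)
    classes = np.unique(y) if task == "svc" else None
    if task == "svc" and classes.size != 2:
        raise ValueError("classification requires exactly two classes")
    grid = grid or default_grid(task)

    preds = np.full((cv.n, cv.r), np.nan, dtype=object if task == "svc" else float)
    scores = np.full((cv.n, cv.r), np.nan) if task == "svc" else None
    members_out: list[MemberModel] = []
    n_degenerate = 0
    for member in cache.members:
        y_tr = y[member.train_idx]
        degenerate = (task == "svr" and np.ptp(y_tr.astype(float)) == 0) or \
                     (task == "svc" and np.unique(y_tr).size < 2)
        if degenerate:
            n_degenerate += 1
            continue
        y_sd = float(np.std(y_tr.astype(float))) if task == "svr" else 1.0
        settings = _expand_settings(grid, task, y_sd)
        C, eps = _select_setting(member, y, settings, task, classes, seed)
        model = _fit_model(task, member.F_train, y_tr, C, eps, seed)
        if task == "svr":
            preds[member.test_idx, member.rep] = model.predict(member.F_test)
        else:
            preds[member.test_idx, member.rep] = model.predict(member.F_test)
            scores[member.test_idx, member.rep] = model.decision_function(member.F_test)
        if want_members:
            coef = model.coef_.ravel()
            icpt = float(np.atleast_1d(model.intercept_)[0])
            w_vox, w_const = backproject_weights(member.chain, coef, icpt)
            members_out.append(MemberModel(
                rep=member.rep, fold=member.fold, chain=member.chain,
                params={"C": C, "epsilon": eps}, coef=coef, intercept=icpt,
                voxel_weights=w_vox, voxel_const=w_const))
    if n_degenerate > 0.2 * len(cache.members):
        raise RuntimeError(
            f"{n_degenerate}/{len(cache.members)} degenerate CV members")
    return preds, scores, members_out, classes


def _prediction_table(ids, y, preds, scores, task, classes) -> pd.DataFrame:
    r = preds.shape[1]
    out = pd.DataFrame({"id": ids, "y_true": y})
    if task == "svr":
        for j in range(r):
            out[f"pred_rep_{j + 1}"] = preds[:, j].astype(float)
        out["ensemble"] = np.nanmean(preds.astype(float), axis=1)
    else:
        for j in range(r):
            out[f"pred_rep_{j + 1}"] = preds[:, j]
            out[f"score_rep_{j + 1}"] = scores[:, j]
        out["decision_score"] = np.nanmean(scores, axis=1)
        out["ensemble"] = np.where(out["decision_score"] > 0, classes[1], classes[0])
    return out


def train_nested(gmv: GMVMatrix, covariates: pd.DataFrame | None, y,
                 cv: CVAssignment, task: str = "svr", grid: dict | None = None,
                 chain_config: ChainConfig | None = None, seed: int = 0,
                 cache: FeatureCache | None = None):
    """Run the full nested CV cycle; returns (TrainedEnsemble, PredictionTable)."""
    y = np.asarray(y)
    if cache is None:
        cache = build_feature_cache(gmv, covariates, cv, chain_config)
    preds, scores, members, classes = _train_on_cache(
        cache, y, task, grid, seed, want_members=True)
    ids = gmv.subject_ids if gmv.subject_ids is not None else np.arange(cv.n)
    table = _prediction_table(ids, y, preds, scores, task, classes)
    ensemble = TrainedEnsemble(task=task, cv=cv, members=members,
                               classes=classes, grid=grid or default_grid(task))
    return ensemble, table


# --------------------------------------------------------------------------
# evaluation


def evaluate_regression(pred: pd.DataFrame) -> dict:
    """MAE, R² and Pearson r of ensemble-mean predictions vs truth."""
    y = pred["y_true"].to_numpy(dtype=float)
    yhat = pred["ensemble"].to_numpy(dtype=float)
    ok = ~np.isnan(yhat) & ~np.isnan(y)
    y, yhat = y[ok], yhat[ok]
    if y.size < 2:
        raise ValueError("need at least 2 subjects")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero label variance: R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    r = float(np.corrcoef(yhat, y)[0, 1]) if np.std(yhat) > 0 else np.nan
    return {"MAE": float(np.mean(np.abs(yhat - y))),
            "R2": 1.0 - ss_res / ss_tot, "r": r, "n": int(y.size)}


def evaluate_classification(pred: pd.DataFrame, positive=None) -> dict:
    """Balanced accuracy = (sensitivity + specificity) / 2 on ensemble labels."""
    y = pred["y_true"].to_numpy()
    yhat = pred["ensemble"].to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need both classes present in truth")
    pos = positive if positive is not None else classes[1]
    neg = classes[classes != pos][0]
    sens = float(np.mean(yhat[y == pos] == pos))
    spec = float(np.mean(yhat[y == neg] == neg))
    return {"BAC": (sens + spec) / 2.0, "sensitivity": sens,
            "specificity": spec, "n": int(y.size)}


# --------------------------------------------------------------------------
# permutation significance


@dataclass
class PermutationResult:
    p: float
    observed: float
    null: np.ndarray
    statistic: str
    n_perm: int


def permutation_significance(gmv: GMVMatrix, covariates, y, cv: CVAssignment,
                             task: str = "svr", grid: dict | None = None,
                             chain_config: ChainConfig | None = None,
                             n_perm: int = 1000, seed: int = 0,
                             statistic: str | None = None,
                             cache: FeatureCache | None = None
                             ) -> PermutationResult:
    """Label-permutation test of the whole nested pipeline.

    Labels are permuted across subjects while the CV assignment (and hence
    every label-independent preprocessing chain) stays fixed; the full
    model selection + refit runs per permutation.  ``p = (1 + #{permuted
    statistic at least as good}) / (1 + n_perm)``, where "as good" means
    <= for MAE and >= for BAC.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    statistic = statistic or ("MAE" if task == "svr" else "BAC")
    y = np.asarray(y)
    if cache is None:
        cache = build_feature_cache(gmv, covariates, cv, chain_config)

    def stat(labels: np.ndarray) -> float:
        preds, scores, _, classes = _train_on_cache(
            cache, labels, task, grid, seed, want_members=False)
        if task == "svr":
            yhat = np.nanmean(preds.astype(float), axis=1)
            return float(np.mean(np.abs(yhat - labels.astype(float))))
        dec = np.nanmean(scores, axis=1)
        yhat = np.where(dec > 0, classes[1], classes[0])
        return _bac(labels, yhat, classes)

    observed = stat(y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = stat(y[rng.permutation(y.size)])
    better = null <= observed if statistic == "MAE" else null >= observed
    p = (1.0 + int(better.sum())) / (1.0 + n_perm)
    return PermutationResult(p=p, observed=observed, null=null,
                             statistic=statistic, n_perm=n_perm)


# --------------------------------------------------------------------------
# external application


def apply_ensemble(ensemble: TrainedEnsemble, gmv: GMVMatrix,
                   covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Predict new subjects with every ensemble member; per-repetition means
    and the grand ensemble mean are reported (decision scores likewise for
    classifiers)."""
    n = gmv.n_subjects
    r = ensemble.cv.r
    sums = np.zeros((n, r))
    counts = np.zeros(r)
    for mm in ensemble.members:
        F = mm.chain.transform(gmv, covariates)
        dec = F @ mm.coef + mm.intercept
        sums[:, mm.rep] += dec
        counts[mm.rep] += 1
    if np.any(counts == 0):
        raise RuntimeError("a repetition has no trained members")
    per_rep = sums / counts
    ids = gmv.subject_ids if gmv.subject_ids is not None else np.arange(n)
    out = pd.DataFrame({"id": ids})
    if ensemble.task == "svr":
        for j in range(r):
            out[f"pred_rep_{j + 1}"] = per_rep[:, j]
        out["ensemble"] = per_rep.mean(axis=1)
    else:
        for j in range(r):
            out[f"score_rep_{j + 1}"] = per_rep[:, j]
        out["decision_score"] = per_rep.mean(axis=1)
        out["ensemble"] = np.where(out["decision_score"] > 0,
                                   ensemble.classes[1], ensemble.classes[0])
    return out
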