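"""Sparse partial least squares (SPLS) between clinical and voxel matrices.

Given a column-standardized clinical matrix X (n x p, e.g. six features:
BMI gap, disease expression score, symptom total, age of onset, illness
duration, hospitalizations) and a voxel matrix Y (n x q, overlap-region
grey matter), SPLS extracts successive *latent variables*: sparse weight
pairs (u, v) maximizing the cross-covariance u' X'Y v subject to unit L2
norms and L1 (lasso) constraints ``||u||_1 <= c_u``, ``||v||_1 <= c_v``.
Each rank-1 fit is the penalized matrix decomposition: alternating
soft-thresholded power iterations where the threshold is found by bisection
so the L1 constraint just binds.  With the constraints released
(``c = sqrt(dim)``) the solution coincides with the leading singular vector
pair of X'Y.

Latent-variable significance is assessed by refitting under row
permutations of X (statistic: the latent-score correlation rho), sparsity
is selected by k-fold cross-validated out-of-fold rho, weight stability by
case-resampling bootstrap, and successive LVs are obtained after projection
deflation of both matrices on their latent scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["LatentVariable", "SPLSModel", "SPLSConfig", "standardize_columns",
           "fit_rank1", "deflate", "permutation_test_lv", "select_sparsity",
           "bootstrap_weights", "fit_spls"]


def standardize_columns(A: np.ndarray) -> np.ndarray:
    """Column z-scoring (population SD); constant columns become zero."""
    A = np.asarray(A, dtype=float)
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (A - mu) / sd


def _soft(w: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(w) * np.maximum(np.abs(w) - delta, 0.0)


def _l1_unit(w: np.ndarray, c: float | None) -> np.ndarray:
    """Soft-threshold and L2-normalize so that ||out||_1 <= c, ||out||_2 = 1.

    The threshold is the smallest delta >= 0 satisfying the constraint,
    found by bisection (the L1 norm of the normalized vector is
    non-increasing in delta)."""
    nrm = np.linalg.norm(w)
    if nrm == 0:
        return np.zeros_like(w)
    out = w / nrm
    if c is None or np.abs(out).sum() <= c:
        return out
    lo, hi = 0.0, float(np.abs(w).max())
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        s = _soft(w, mid)
        ns = np.linalg.norm(s)
        if ns == 0 or np.abs(s / ns).sum() > c:
            # ns == 0 only at mid == max|w| boundary; push hi down then
            if ns == 0:
                hi = mid
            else:
                lo = mid
        else:
            hi = mid
    s = _soft(w, hi)
    ns = np.linalg.norm(s)
    if ns == 0:  # keep at least the largest entry
        j = int(np.argmax(np.abs(w)))
        s = np.zeros_like(w)
        s[j] = np.sign(w[j])
        ns = 1.0
    return s / ns


@dataclass
class LatentVariable:
    index: int
    u: np.ndarray  # clinical weights, ||u||2 <= 1, sparse
    v: np.ndarray  # voxel weights
    d: float  # singular value u' X'Y v
    rho: float  # cor(Xu, Yv)
    p: float | None = None
    c_u: float | None = None
    c_v: float | None = None
    bootstrap: dict | None = None
    degenerate: bool = False
    converged: bool = True


@dataclass
class SPLSConfig:
    c_u: float | None = None
    c_v: float | None = None
    sparsity_grid: list | None = None  # list of (c_u, c_v)
    select_folds: int = 5
    n_perm: int = 500
    alpha: float = 0.05
    max_lv: int = 5
    n_boot: int = 0
    tol: float = 1e-6
    max_iter: int = 500


@dataclass
class SPLSModel:
    lvs: list
    config: SPLSConfig
    n: int = 0
    feature_names: list | None = None

    @property
    def n_significant(self) -> int:
        return len(self.lvs)


def _rho(X, Y, u, v) -> float:
    xi, om = X @ u, Y @ v
    if np.std(xi) == 0 or np.std(om) == 0:
        return 0.0
    return float(np.corrcoef(xi, om)[0, 1])


def fit_rank1(X: np.ndarray, Y: np.ndarray, c_u: float | None = None,
              c_v: float | None = None, tol: float = 1e-6,
              max_iter: int = 500) -> LatentVariable:
    """One penalized rank-1 decomposition of M = X'Y.

    Sign convention: the largest-|weight| clinical entry of u is positive
    (u and v are flipped together, leaving d unchanged)."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    M = X.T @ Y
    p, q = M.shape
    if c_u is not None and not (1.0 <= c_u <= np.sqrt(p) + 1e-9):
        raise ValueError("c_u must lie in [1, sqrt(p)]")
    if c_v is not None and not (1.0 <= c_v <= np.sqrt(q) + 1e-9):
        raise ValueError("c_v must lie in [1, sqrt(q)]")
    if not np.any(M):
        log.warning("X'Y is identically zero: degenerate LV")
        return LatentVariable(0, np.zeros(p), np.zeros(q), 0.0, 0.0,
                              degenerate=True)
    # initialize v from the leading right singular vector of M
    _, _, Vt = np.linalg.svd(M, full_matrices=False)
    v = Vt[0]
    u = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        u_new = _l1_unit(M @ v, c_u)
        v_new = _l1_unit(M.T @ u_new, c_v)
        delta = max(np.abs(u_new - u).max(), np.abs(v_new - v).max())
        u, v = u_new, v_new
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("rank-1 fit did not converge in %d iterations", max_iter)
    j = int(np.argmax(np.abs(u)))
    if u[j] < 0:
        u, v = -u, -v
    d = float(u @ M @ v)
    return LatentVariable(0, u, v, d, _rho(X, Y, u, v), c_u=c_u, c_v=c_v,
                          converged=converged)


def deflate(X: np.ndarray, Y: np.ndarray, u: np.ndarray, v: np.ndarray):
    """Projection deflation: remove each matrix's latent-score direction."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    xi = X @ u
    om = Y @ v
    nx, ny = float(xi @ xi), float(om @ om)
    if nx > 0:
        X = X - np.outer(xi, xi @ X) / nx
    else:
        log.warning("zero-norm clinical score: X deflation skipped")
    if ny > 0:
        Y = Y - np.outer(om, om @ Y) / ny
    else:
        log.warning("zero-norm voxel score: Y deflation skipped")
    return X, Y


def permutation_test_lv(X: np.ndarray, Y: np.ndarray, lv: LatentVariable,
                        n_perm: int = 500, seed: int = 0,
                        tol: float = 1e-6, max_iter: int = 500) -> float:
    """Row-permute X, refit at the same sparsity, compare latent rho."""
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    count = 0
    for _ in range(n_perm):
        Xp = X[rng.permutation(n)]
        lv_p = fit_rank1(Xp, Y, lv.c_u, lv.c_v, tol=tol, max_iter=max_iter)
        if lv_p.rho >= lv.rho:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


def select_sparsity(X: np.ndarray, Y: np.ndarray, grid,
                    k_folds: int = 5, seed: int = 0) -> tuple:
    """Grid point maximizing mean out-of-fold latent correlation in k-fold
    CV; ties break toward the sparser pair (smaller c_u + c_v)."""
    grid = list(grid)
    if not grid:
        raise ValueError("sparsity grid is empty")
    if len(grid) == 1:
        return tuple(grid[0])
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)
    best, best_score = None, -np.inf
    for c_u, c_v in sorted(grid, key=lambda g: (g[0] + g[1], g)):
        scores = []
        for f in folds:
            mask = np.ones(n, dtype=bool)
            mask[f] = False
            lv = fit_rank1(X[mask], Y[mask], c_u, c_v)
            scores.append(_rho(X[f], Y[f], lv.u, lv.v))
        score = float(np.mean(scores))
        if score > best_score:  # strict: first (sparsest) wins ties
            best, best_score = (c_u, c_v), score
    return best


def bootstrap_weights(X: np.ndarray, Y: np.ndarray, c_u, c_v,
                      n_boot: int = 500, seed: int = 0,
                      reference: LatentVariable | None = None) -> dict:
    """Case-resampling bootstrap of the rank-1 weights.

    Each resample is refit at the same sparsity and sign-aligned to the
    original fit; returns per-weight 95% percentile CIs and nonzero
    selection frequencies.  Resamples with a constant column are skipped
    (counted in ``n_skipped``)."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ref = reference or fit_rank1(X, Y, c_u, c_v)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    us, vs = [], []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb, Yb = X[idx], Y[idx]
        if np.any(Xb.std(axis=0) == 0) or np.any(Yb.std(axis=0) == 0):
            skipped += 1
            continue
        lv = fit_rank1(Xb, Yb, c_u, c_v)
        if lv.u @ ref.u + lv.v @ ref.v < 0:
            lv.u, lv.v = -lv.u, -lv.v
        us.append(lv.u)
        vs.append(lv.v)
    U, V = np.asarray(us), np.asarray(vs)
    out = {"n_boot": n_boot, "n_used": len(us), "n_skipped": skipped}
    for name, W in (("u", U), ("v", V)):
        out[f"{name}_ci_lo"] = np.percentile(W, 2.5, axis=0)
        out[f"{name}_ci_hi"] = np.percentile(W, 97.5, axis=0)
        out[f"{name}_selection_freq"] = (W != 0).mean(axis=0)
    return out


def fit_spls(X: np.ndarray, Y: np.ndarray, config: SPLSConfig | None = None,
             seed: int = 0, feature_names=None) -> SPLSModel:
    """Extract successive LVs until one fails the permutation test or
    ``max_lv`` is reached.  X and Y must be column-standardized."""
    cfg = config or SPLSConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have equal row counts")
    lvs: list[LatentVariable] = []
    Xd, Yd = X, Y
    rng = np.random.default_rng(seed)
    for i in range(cfg.max_lv):
        c_u, c_v = cfg.c_u, cfg.c_v
        if cfg.sparsity_grid:
            c_u, c_v = select_sparsity(Xd, Yd, cfg.sparsity_grid,
                                       cfg.select_folds,
                                       seed=int(rng.integers(2 ** 31)))
        lv = fit_rank1(Xd, Yd, c_u, c_v, tol=cfg.tol, max_iter=cfg.max_iter)
        if lv.degenerate:
            break
        lv.index = i + 1
        lv.p = permutation_test_lv(Xd, Yd, lv, cfg.n_perm,
                                   seed=int(rng.integers(2 ** 31)),
                                   tol=cfg.tol, max_iter=cfg.max_iter)
        if lv.p >= cfg.alpha:
            break
        if cfg.n_boot >= 100:
            lv.bootstrap = bootstrap_weights(
                Xd, Yd, c_u, c_v, cfg.n_boot,
                seed=int(rng.integers(2 ** 31)), reference=lv)
        lvs.append(lv)
        Xd, Yd = deflate(Xd, Yd, lv.u, lv.v)
    return SPLSModel(lvs=lvs, config=cfg, n=X.shape[0],
                     feature_names=list(feature_names) if feature_names else None)
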