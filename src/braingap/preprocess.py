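"""In-fold preprocessing chain for voxel (or tabular) feature matrices.

The chain applies, in order: optional median imputation, Gaussian smoothing
(mask-renormalized, parameter-free), per-voxel residualization of
chronological age (OLS slope fitted on training data, residual re-centred on
the training voxel mean), scalar per-site global-mean offset correction, PCA
to a configured cumulative explained variance, and per-component scaling
(min-max to [0, 1] by default).  Every parameter is estimated on training
data only and frozen; applying a fitted chain never refits anything, which
is what keeps nested cross-validation leakage-free.

Because every step after smoothing is affine and voxel-separable until the
PCA rotation, linear model weights in component space pull back exactly to a
per-voxel weight vector plus a constant (:func:`backproject_weights`); the
voxel pattern reproduces the model's decision values on the smoothed,
age/site-corrected voxel stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import GMVMatrix

log = logging.getLogger(__name__)

__all__ = ["ChainConfig", "PreprocChain", "smooth_gmv", "fit_chain",
           "apply_chain", "backproject_weights"]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class ChainConfig:
    """Tunable preprocessing parameters.

    ``pca_variance=None`` skips PCA (identity feature space, used for
    tabular classifiers); ``scaling`` is ``"minmax"``, ``"zscore"`` or
    ``None``.
    """

    smooth_fwhm: float = 2.0  # voxel units; ~6 mm at 3 mm isotropic voxels
    residualize_age: bool = True
    site_correction: bool = True
    pca_variance: float | None = 0.8
    scaling: str | None = "minmax"
    impute: bool = False


def smooth_gmv(gmv: GMVMatrix, fwhm: float) -> GMVMatrix:
    """Per-subject 3-D Gaussian smoothing with edge/mask renormalization.

    The kernel mass is restricted to the analysis mask, so constant images
    stay exactly constant and no intensity leaks in from off-mask voxels.
    ``fwhm=0`` is the identity.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return gmv
    if gmv.grid_shape is None:
        raise ValueError("smoothing requires grid geometry")
    sigma = fwhm / _FWHM_TO_SIGMA
    maskvol = gmv.mask.reshape(gmv.grid_shape).astype(float)
    norm = ndimage.gaussian_filter(maskvol, sigma)
    full = np.zeros((gmv.n_subjects, maskvol.size))
    full[:, gmv.mask] = gmv.data
    out = np.empty_like(gmv.data)
    for i in range(gmv.n_subjects):
        sm = ndimage.gaussian_filter(full[i].reshape(gmv.grid_shape) * maskvol, sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = sm / norm
        out[i] = sm.reshape(-1)[gmv.mask]
    return GMVMatrix(out, gmv.grid_shape, gmv.mask, gmv.subject_ids)


@dataclass
class PreprocChain:
    """Frozen parameters of a fitted preprocessing chain."""

    config: ChainConfig
    grid_shape: tuple | None
    mask: np.ndarray | None
    impute_values: np.ndarray | None
    age_slopes: np.ndarray | None  # (V,)
    age_mean: float | None
    site_offsets: dict[str, float] | None
    grand_mean: float | None
    pca_mean: np.ndarray | None  # (V,)
    components: np.ndarray | None  # (k, V)
    explained_variance_ratio: np.ndarray | None
    scale_a: np.ndarray | None  # min (minmax) or mean (zscore), per component
    scale_b: np.ndarray | None  # max-min or sd, per component
    n_train: int = 0
    degenerate_components: np.ndarray | None = None
    flags: list = field(default_factory=list)

    # -- application ------------------------------------------------------

    def _voxel_stage(self, gmv: GMVMatrix, covariates: pd.DataFrame | None,
                     allow_new_sites: bool = True) -> np.ndarray:
        """Smoothing + age residualization + site correction (no PCA/scaling)."""
        X = np.array(gmv.data, dtype=float)
        if X.shape[1] != (self.pca_mean.size if self.pca_mean is not None
                          else X.shape[1]):
            raise ValueError("voxel count mismatch with fitted chain")
        if self.impute_values is not None:
            nanmask = np.isnan(X)
            if nanmask.any():
                X[nanmask] = np.take(self.impute_values, np.nonzero(nanmask)[1])
        if self.config.smooth_fwhm > 0:
            X = smooth_gmv(GMVMatrix(X, self.grid_shape, self.mask),
                           self.config.smooth_fwhm).data
        if self.age_slopes is not None:
            if X.shape[1] != self.age_slopes.size:
                raise ValueError("voxel count mismatch with fitted chain")
            age = np.asarray(covariates["age"], dtype=float)
            X = X - np.outer(age - self.age_mean, self.age_slopes)
        if self.site_offsets is not None:
            sites = np.asarray(covariates["site"]).astype(str)
            g = X.mean(axis=1)
            offs = np.empty(len(sites))
            for s in np.unique(sites):
                sel = sites == s
                if s in self.site_offsets:
                    offs[sel] = self.site_offsets[s]
                elif allow_new_sites:
                    # unseen site: offset from the application sample itself
                    off = float(g[sel].mean() - self.grand_mean)
                    offs[sel] = off
                    log.info("unseen site %s: offset %.4g estimated at application",
                             s, off)
                else:
                    raise KeyError(f"unknown site {s}")
            X = X - offs[:, None]
        return X

    def transform_voxel_stage(self, gmv: GMVMatrix,
                              covariates: pd.DataFrame | None = None) -> np.ndarray:
        """Public access to the voxel-space stage (pre-PCA); used for the
        back-projection decision-value contract and map diagnostics."""
        return self._voxel_stage(gmv, covariates)

    def transform(self, gmv: GMVMatrix, covariates: pd.DataFrame | None = None,
                  clip: bool = True) -> np.ndarray:
        X = self._voxel_stage(gmv, covariates)
        if self.components is not None:
            T = (X - self.pca_mean) @ self.components.T
        else:
            T = X
        if self.scale_a is not None:
            with np.errstate(invalid="ignore", divide="ignore"):
                T = (T - self.scale_a) / self.scale_b
            if self.degenerate_components is not None and \
                    self.degenerate_components.any():
                T[:, self.degenerate_components] = 0.0
            if self.config.scaling == "minmax" and clip:
                T = np.clip(T, 0.0, 1.0)
        return T


def fit_chain(train_gmv: GMVMatrix, covariates: pd.DataFrame | None = None,
              config: ChainConfig | None = None) -> PreprocChain:
    """Fit the chain on training data only.

    ``covariates`` must carry ``age`` (if residualizing) and ``site`` (if
    site-correcting) aligned with the rows of ``train_gmv``.
    """
    cfg = config or ChainConfig()
    X = np.array(train_gmv.data, dtype=float)
    n = X.shape[0]
    flags: list[str] = []

    impute_values = None
    if cfg.impute:
        impute_values = np.nanmedian(X, axis=0)
        impute_values = np.where(np.isnan(impute_values), 0.0, impute_values)
        nanmask = np.isnan(X)
        if nanmask.any():
            X[nanmask] = np.take(impute_values, np.nonzero(nanmask)[1])

    if cfg.smooth_fwhm > 0:
        X = smooth_gmv(GMVMatrix(X, train_gmv.grid_shape, train_gmv.mask),
                       cfg.smooth_fwhm).data

    age_slopes = age_mean = None
    if cfg.residualize_age:
        if covariates is None or "age" not in covariates:
            raise ValueError("age residualization requires an 'age' covariate")
        age = np.asarray(covariates["age"], dtype=float)
        age_mean = float(age.mean())
        ac = age - age_mean
        denom = float(ac @ ac)
        # zero age variance or zero-variance voxel -> slope 0
        age_slopes = (ac @ X) / denom if denom > 0 else np.zeros(X.shape[1])
        X = X - np.outer(ac, age_slopes)

    site_offsets = grand_mean = None
    if cfg.site_correction:
        if covariates is None or "site" not in covariates:
            raise ValueError("site correction requires a 'site' covariate")
        sites = np.asarray(covariates["site"]).astype(str)
        g = X.mean(axis=1)
        grand_mean = float(g.mean())
        site_offsets = {}
        for s in np.unique(sites):
            sel = sites == s
            if sel.sum() == 1:
                flags.append(f"site {s} has a single training subject")
            site_offsets[str(s)] = float(g[sel].mean() - grand_mean)
        offs = np.array([site_offsets[s] for s in sites])
        X = X - offs[:, None]

    pca_mean = components = evr = None
    if cfg.pca_variance is not None:
        pca_mean = X.mean(axis=0)
        Xc = X - pca_mean
        if X.shape[0] <= X.shape[1]:
            # Gram-matrix route: exact and much faster when n << V
            w, U = np.linalg.eigh(Xc @ Xc.T)
            order = np.argsort(w)[::-1]
            S = np.sqrt(np.maximum(w[order], 0.0))
            nz = S > (S[0] * 1e-12 if S.size and S[0] > 0 else 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                Vt = (Xc.T @ U[:, order][:, nz] / S[nz]).T
            S = S[nz]
        else:
            _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        # deterministic sign: largest-|loading| entry of each component > 0
        if S.size:
            piv = np.argmax(np.abs(Vt), axis=1)
            flip = np.sign(Vt[np.arange(Vt.shape[0]), piv])
            flip[flip == 0] = 1.0
            Vt = Vt * flip[:, None]
        var = S ** 2
        tot = var.sum()
        evr_all = var / tot if tot > 0 else np.zeros_like(var)
        if cfg.pca_variance >= 1.0:
            k = int((S > S[0] * 1e-12).sum()) if S.size else 1
        else:
            k = int(np.searchsorted(np.cumsum(evr_all), cfg.pca_variance) + 1)
        k = max(1, min(k, S.size))
        components = Vt[:k]
        evr = evr_all[:k]
        T = Xc @ components.T
    else:
        T = X

    scale_a = scale_b = degenerate = None
    if cfg.scaling is not None:
        if cfg.scaling == "minmax":
            scale_a, hi = T.min(axis=0), T.max(axis=0)
            scale_b = hi - scale_a
        elif cfg.scaling == "zscore":
            scale_a = T.mean(axis=0)
            scale_b = T.std(axis=0, ddof=0)
        else:
            raise ValueError(f"unknown scaling {cfg.scaling!r}")
        degenerate = scale_b <= 0
        if degenerate.any():
            flags.append(f"{int(degenerate.sum())} degenerate scaling component(s)")
            scale_b = np.where(degenerate, 1.0, scale_b)

    return PreprocChain(
        config=cfg, grid_shape=train_gmv.grid_shape, mask=train_gmv.mask,
        impute_values=impute_values, age_slopes=age_slopes, age_mean=age_mean,
        site_offsets=site_offsets, grand_mean=grand_mean, pca_mean=pca_mean,
        components=components, explained_variance_ratio=evr,
        scale_a=scale_a, scale_b=scale_b, n_train=n,
        degenerate_components=degenerate, flags=flags,
    )


def apply_chain(chain: PreprocChain, gmv: GMVMatrix,
                covariates: pd.DataFrame | None = None,
                clip: bool = True) -> np.ndarray:
    """Apply a fitted chain with frozen parameters to (new) data."""
    return chain.transform(gmv, covariates, clip=clip)


def backproject_weights(chain: PreprocChain, weights: np.ndarray,
                        intercept: float = 0.0):
    """Pull component-space linear model weights back to voxel space.

    Returns ``(w_voxel, const)`` such that for any input ``X`` at the
    voxel stage (smoothed, age/site-corrected, un-clipped),
    ``X @ w_voxel + const`` equals the model's decision values exactly.
    Degenerate (zero-range) components contribute nothing.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if chain.scale_b is not None:
        w_eff = w / chain.scale_b
        if chain.degenerate_components is not None and \
                chain.degenerate_components.any():
            w_eff = np.where(chain.degenerate_components, 0.0, w_eff)
            log.info("degenerate component weights zeroed in back-projection")
        a_term = float(w_eff @ chain.scale_a)
    else:
        w_eff, a_term = w, 0.0
    if chain.components is not None:
        w_voxel = chain.components.T @ w_eff
        const = float(intercept) - float(chain.pca_mean @ w_voxel) - a_term
    else:
        w_voxel = w_eff
        const = float(intercept) - a_term
    return w_voxel, const
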