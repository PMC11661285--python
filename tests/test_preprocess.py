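"""Preprocessing chain: smoothing, leakage-free fitting, back-projection."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from braingap.io import GMVMatrix
from braingap.preprocess import (ChainConfig, apply_chain, backproject_weights,
                                 fit_chain, smooth_gmv)


def make_gmv(rng, n=40, grid=(4, 4, 4)):
    V = int(np.prod(grid))
    return GMVMatrix(0.5 + 0.05 * rng.normal(size=(n, V)), grid)


def make_cov(rng, n=40, n_sites=3):
    return pd.DataFrame({"age": rng.uniform(15, 75, n),
                         "site": [f"s{i % n_sites}" for i in range(n)]})


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, rng):
        g = make_gmv(rng)
        assert smooth_gmv(g, 0.0) is g

    def test_constant_image_preserved(self):
        g = GMVMatrix(np.full((3, 64), 0.7), (4, 4, 4))
        sm = smooth_gmv(g, 2.0)
        assert np.allclose(sm.data, 0.7, atol=1e-12)

    def test_impulse_center_matches_kernel_peak(self):
        """A unit impulse smoothed on an unmasked grid reproduces the
        (renormalized) Gaussian kernel value at the centre voxel."""
        grid = (9, 9, 9)
        data = np.zeros((1, 9 ** 3))
        center = np.ravel_multi_index((4, 4, 4), grid)
        data[0, center] = 1.0
        fwhm = 2.0
        sm = smooth_gmv(GMVMatrix(data, grid), fwhm)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        impulse = np.zeros(grid)
        impulse[4, 4, 4] = 1.0
        expect = ndimage.gaussian_filter(impulse, sigma)[4, 4, 4]
        assert np.isclose(sm.data[0, center], expect, rtol=1e-10)

    def test_negative_fwhm_rejected(self, rng):
        with pytest.raises(ValueError):
            smooth_gmv(make_gmv(rng), -1.0)


class TestChainFit:
    def test_age_residualization_decorrelates_training_features(self, rng):
        n = 60
        g = make_gmv(rng, n)
        cov = make_cov(rng, n)
        # inject a strong age effect
        g.data += np.outer(cov["age"] - 45, rng.normal(0, 0.01, g.n_voxels))
        chain = fit_chain(g, cov, ChainConfig(smooth_fwhm=0, pca_variance=None,
                                              scaling=None,
                                              site_correction=False))
        X = chain.transform_voxel_stage(g, cov)
        ac = cov["age"] - cov["age"].mean()
        num = ac.to_numpy() @ (X - X.mean(axis=0))
        denom = np.linalg.norm(ac) * np.linalg.norm(X - X.mean(axis=0), axis=0)
        assert np.max(np.abs(num / denom)) < 1e-10

    def test_null_age_effect_slopes_near_zero(self, rng):
        n = 200
        g = make_gmv(rng, n)
        cov = make_cov(rng, n)
        chain = fit_chain(g, cov, ChainConfig(smooth_fwhm=0))
        # noise-only voxels: slope SE ~ sd_noise / (sd_age * sqrt(n))
        se = 0.05 / (np.std(cov["age"]) * np.sqrt(n))
        assert np.max(np.abs(chain.age_slopes)) < 5 * se

    def test_single_site_offsets_zero(self, rng):
        g = make_gmv(rng)
        cov = make_cov(rng, n_sites=1)
        chain = fit_chain(g, cov, ChainConfig(smooth_fwhm=0))
        assert np.allclose(list(chain.site_offsets.values()), 0.0, atol=1e-12)

    def test_full_variance_pca_round_trip(self, rng):
        """retained variance 1.0: PCA is an orthogonal rotation, and
        inverting scaling+rotation reproduces the voxel-stage data."""
        g = make_gmv(rng, n=80, grid=(4, 4, 2))
        cov = make_cov(rng, 80)
        chain = fit_chain(g, cov, ChainConfig(smooth_fwhm=0, pca_variance=1.0))
        F = chain.transform(g, cov)
        X_stage = chain.transform_voxel_stage(g, cov)
        # invert: unscale, rotate back, add mean
        T = F * chain.scale_b + chain.scale_a
        X_rec = T @ chain.components + chain.pca_mean
        assert np.allclose(X_rec, X_stage, atol=1e-8)

    def test_apply_to_training_reproduces_fit(self, rng):
        g = make_gmv(rng)
        cov = make_cov(rng)
        chain = fit_chain(g, cov, ChainConfig(smooth_fwhm=0))
        F1 = chain.transform(g, cov)
        F2 = apply_chain(chain, g, cov)
        assert np.array_equal(F1, F2)

    def test_row_permutation_equivariance(self, rng):
        g = make_gmv(rng)
        cov = make_cov(rng)
        chain = fit_chain(g, cov, ChainConfig(smooth_fwhm=0))
        perm = rng.permutation(g.n_subjects)
        F = apply_chain(chain, g, cov)
        Fp = apply_chain(chain, g.select(perm),
                         cov.iloc[perm].reset_index(drop=True))
        assert np.allclose(F[perm], Fp, atol=1e-12)

    def test_extreme_subject_clipped_no_exception(self, rng):
        g = make_gmv(rng)
        cov = make_cov(rng)
        chain = fit_chain(g, cov, ChainConfig(smooth_fwhm=0))
        g2 = GMVMatrix(g.data[:3] * 10 + 3.0, g.grid_shape)
        F = apply_chain(chain, g2, cov.iloc[:3])
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_unseen_site_estimated_from_application_sample(self, rng):
        g = make_gmv(rng)
        cov = make_cov(rng)
        chain = fit_chain(g, cov, ChainConfig(smooth_fwhm=0, pca_variance=None,
                                              scaling=None))
        cov_new = cov.iloc[:5].copy()
        cov_new["site"] = "new_site"
        offset = 0.3
        g_new = GMVMatrix(g.data[:5] + offset, g.grid_shape)
        X = apply_chain(chain, g_new, cov_new)
        X_ref = chain.transform_voxel_stage(g.select(np.arange(5)), cov.iloc[:5])
        # the constant site offset is absorbed by the application-sample mean
        assert np.allclose(X.mean(), X_ref.mean(), atol=0.05)

    def test_voxel_mismatch_raises(self, rng):
        g = make_gmv(rng)
        cov = make_cov(rng)
        chain = fit_chain(g, cov, ChainConfig(smooth_fwhm=0))
        bad = GMVMatrix(rng.normal(size=(4, 10)), None)
        with pytest.raises(ValueError):
            apply_chain(chain, bad, cov.iloc[:4])

    def test_no_leakage_sentinel(self, rng):
        """Corrupting held-out rows never changes the fitted chain."""
        g = make_gmv(rng, n=50)
        cov = make_cov(rng, 50)
        train = np.arange(40)
        chain1 = fit_chain(g.select(train), cov.iloc[train],
                           ChainConfig(smooth_fwhm=0))
        g2 = GMVMatrix(g.data.copy(), g.grid_shape)
        g2.data[40:] += 100.0  # corrupt test rows only
        chain2 = fit_chain(g2.select(train), cov.iloc[train],
                           ChainConfig(smooth_fwhm=0))
        assert np.array_equal(chain1.components, chain2.components)
        assert np.array_equal(chain1.age_slopes, chain2.age_slopes)
        assert chain1.site_offsets == chain2.site_offsets


class TestBackprojection:
    def test_identity_pca_unit_scaling_weights_pass_through(self, rng):
        g = make_gmv(rng)
        cov = make_cov(rng)
        chain = fit_chain(g, cov, ChainConfig(smooth_fwhm=0, pca_variance=None,
                                              scaling=None))
        w = rng.normal(size=g.n_voxels)
        w_vox, const = backproject_weights(chain, w, 1.5)
        assert np.allclose(w_vox, w)
        assert np.isclose(const, 1.5)

    def test_decision_value_reproduction(self, rng):
        g = make_gmv(rng, n=60)
        cov = make_cov(rng, 60)
        chain = fit_chain(g, cov, ChainConfig(smooth_fwhm=0, pca_variance=0.9))
        F = chain.transform(g, cov)
        w = rng.normal(size=F.shape[1])
        b = -0.7
        decisions = F @ w + b
        w_vox, const = backproject_weights(chain, w, b)
        X_stage = chain.transform_voxel_stage(g, cov)
        assert np.max(np.abs(X_stage @ w_vox + const - decisions)) < 1e-8

    def test_single_component_map_proportional_to_loading(self, rng):
        g = make_gmv(rng)
        cov = make_cov(rng)
        g.data += np.outer(rng.normal(size=g.n_subjects),
                           rng.normal(size=g.n_voxels))  # one strong direction
        chain = fit_chain(g, cov, ChainConfig(smooth_fwhm=0, pca_variance=0.5))
        if chain.components.shape[0] == 1:
            w_vox, _ = backproject_weights(chain, np.array([2.0]), 0.0)
            cos = abs(w_vox @ chain.components[0]) / (
                np.linalg.norm(w_vox) * np.linalg.norm(chain.components[0]))
            assert cos > 1 - 1e-12

    def test_degenerate_component_contributes_zero(self, rng):
        g = make_gmv(rng)
        g.data[:, 0] = 0.5  # constant voxel
        cov = make_cov(rng)
        chain = fit_chain(g, cov, ChainConfig(smooth_fwhm=0, pca_variance=None,
                                              scaling="minmax",
                                              residualize_age=False,
                                              site_correction=False))
        assert chain.degenerate_components[0]
        w = np.ones(g.n_voxels)
        w_vox, _ = backproject_weights(chain, w, 0.0)
        assert w_vox[0] == 0.0
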