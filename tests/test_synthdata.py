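"""Generator contracts: determinism, overlap geometry, truth reconstruction."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from braingap import synthdata as sd


class TestAtlas:
    def test_overlap_matches_request_within_one_voxel(self):
        atlas = sd.make_phantom_atlas((12, 12, 12), 8, (60, 60), 0.5, seed=1)
        assert abs(int(atlas.overlap_mask.sum()) - 30) <= 1
        assert atlas.bmi_mask.sum() == 60
        assert atlas.disease_mask.sum() == 60

    def test_zero_overlap_gives_disjoint_signatures(self):
        atlas = sd.make_phantom_atlas((12, 12, 12), 8, (60, 60), 0.0, seed=1)
        assert int(atlas.overlap_mask.sum()) == 0

    def test_same_seed_identical_atlases(self):
        a = sd.make_phantom_atlas(seed=3)
        b = sd.make_phantom_atlas(seed=3)
        assert np.array_equal(a.bmi_signature, b.bmi_signature)
        assert np.array_equal(a.disease_signature, b.disease_signature)
        assert np.array_equal(a.region_labels, b.region_labels)

    @pytest.mark.parametrize("which", ["bmi", "disease"])
    def test_signatures_are_contiguous_blobs(self, which):
        atlas = sd.make_phantom_atlas((10, 10, 10), 6, (40, 40), 0.5, seed=5)
        sig = atlas.bmi_mask if which == "bmi" else atlas.disease_mask
        vol = sig.reshape(atlas.grid_shape)
        _, n_blobs = ndimage.label(vol)
        assert n_blobs == 1

    def test_negative_sign_dominance(self):
        atlas = sd.make_phantom_atlas(seed=2, neg_fraction=0.8)
        w = atlas.bmi_signature[atlas.bmi_mask]
        assert np.isclose((w < 0).mean(), 0.8, atol=0.02)

    def test_signature_too_large_raises(self):
        with pytest.raises(sd.SizingError):
            sd.make_phantom_atlas((4, 4, 4), 2, (100, 10), 0.5, seed=0)

    def test_small_grid_rejected(self):
        with pytest.raises(sd.ConfigError):
            sd.make_phantom_atlas((3, 4, 4), 2, (5, 5), 0.5, seed=0)


class TestCohort:
    def test_determinism(self, small_atlas):
        cfg = sd.CohortConfig(group_sizes={"HC": 40})
        t1, g1, _ = sd.simulate_cohort(small_atlas, cfg, seed=9)
        t2, g2, _ = sd.simulate_cohort(small_atlas, cfg, seed=9)
        pd.testing.assert_frame_equal(t1, t2)
        assert np.array_equal(g1.data, g2.data)

    def test_null_config_no_voxel_bmi_correlation(self, small_atlas):
        cfg = sd.CohortConfig(group_sizes={"HC": 500}, beta_bmi=0.0,
                              beta_disease={}, age_slope_mean=0.0,
                              age_slope_sd=0.0, gap_sd=0.0)
        t, g, _ = sd.simulate_cohort(small_atlas, cfg, seed=21)
        bmi = t["bmi"].to_numpy()
        bc = bmi - bmi.mean()
        X = g.data - g.data.mean(axis=0)
        r = (bc @ X) / (np.linalg.norm(bc) * np.linalg.norm(X, axis=0))
        assert np.max(np.abs(r)) < 3.0 / np.sqrt(len(t)) * 2.5  # max over 64 voxels

    def test_noiseless_single_site_exactly_linear_in_bmi(self, small_atlas):
        cfg = sd.CohortConfig(group_sizes={"HC": 30}, n_sites=1,
                              noise_sd=0.0, age_slope_mean=0.0,
                              age_slope_sd=0.0, sex_effect_sd=0.0,
                              site_offset_sd=0.0, gap_sd=0.0)
        t, g, tr = sd.simulate_cohort(small_atlas, cfg, seed=5)
        v = np.flatnonzero(small_atlas.bmi_mask)[0]
        x = g.data[:, v]
        expect = cfg.baseline + cfg.beta_bmi * \
            (t["bmi"].to_numpy() - cfg.bmi_mean) * small_atlas.bmi_signature[v]
        assert np.allclose(x, expect, atol=1e-12)

    def test_mass_univariate_recovery_default_config(self, default_atlas):
        """Default SNR, n=600: age-partialed voxel-on-BMI regression recovers
        >=90% of seeded voxels at BH q<0.05."""
        t, g, _ = sd.simulate_cohort(default_atlas, sd.CohortConfig(), seed=33)
        n = len(t)
        bmi = t["bmi"].to_numpy()
        age = t["age"].to_numpy()
        # partial out age from both sides
        A = np.column_stack([np.ones(n), age])
        X = g.data - A @ np.linalg.lstsq(A, g.data, rcond=None)[0]
        y = bmi - A @ np.linalg.lstsq(A, bmi, rcond=None)[0]
        r = (y @ X) / (np.linalg.norm(y) * np.linalg.norm(X, axis=0))
        tstat = r * np.sqrt((n - 3) / (1 - r ** 2))
        p = 2 * stats.t.sf(np.abs(tstat), df=n - 3)
        q = stats.false_discovery_control(p, method="bh")
        sig = default_atlas.bmi_mask
        recovery = (q[sig] < 0.05).mean()
        assert recovery >= 0.90

    def test_age_bmi_correlation_near_config(self, default_atlas):
        t, _, _ = sd.simulate_cohort(
            default_atlas, sd.CohortConfig(group_sizes={"HC": 2000}), seed=3)
        r = np.corrcoef(t["age"], t["bmi"])[0, 1]
        assert abs(r - 0.25) < 0.06

    def test_bmi_within_range(self, hc_cohort):
        t = hc_cohort[0]
        assert t["bmi"].between(18.5, 35.0).all()
        assert t["age"].between(15, 75).all()

    def test_bad_group_size_raises(self, small_atlas):
        with pytest.raises(sd.ConfigError):
            sd.simulate_cohort(small_atlas,
                               sd.CohortConfig(group_sizes={"HC": -1}), seed=0)

    def test_truth_reconstruction_residual_is_drawn_noise(self, small_atlas):
        """Residual after removing every systematic component equals the
        drawn noise: halving noise_sd halves the residual elementwise."""
        kw = dict(group_sizes={"HC": 25, "SCZ": 10})
        c1 = sd.CohortConfig(noise_sd=0.04, **kw)
        c2 = sd.CohortConfig(noise_sd=0.02, **kw)
        t1, g1, tr1 = sd.simulate_cohort(small_atlas, c1, seed=8)
        t2, g2, tr2 = sd.simulate_cohort(small_atlas, c2, seed=8)
        r1 = g1.data - sd.reconstruct_systematic(small_atlas, t1, tr1, c1)
        r2 = g2.data - sd.reconstruct_systematic(small_atlas, t2, tr2, c2)
        assert np.allclose(r1, 2.0 * r2, atol=1e-12)

    def test_propensity_independent_of_bmi(self, small_atlas):
        t, _, tr = sd.simulate_cohort(
            small_atlas, sd.CohortConfig(group_sizes={"HC": 3000}), seed=17)
        r = np.corrcoef(tr.propensity, t["bmi"])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(t))


class TestLongitudinal:
    def test_zero_coupling_no_correlation(self, small_atlas):
        cfg = sd.CohortConfig(group_sizes={"HC": 800})
        t, _, tr = sd.simulate_cohort(small_atlas, cfg, seed=2)
        t2 = sd.simulate_longitudinal(t, tr, gamma=(0.0, 0.0), age_coef=0.0,
                                      missing_rate=(0.0, 0.0), seed=3)
        dw = t2["weight_t2"] - t2["weight_t0"]
        r = np.corrcoef(tr.propensity, dw)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(t2))

    def test_noiseless_change_equals_gamma_times_propensity(self, small_atlas):
        t, _, tr = sd.simulate_cohort(
            small_atlas, sd.CohortConfig(group_sizes={"HC": 50}), seed=2)
        t2 = sd.simulate_longitudinal(t, tr, gamma=(0.5, 1.0), noise_sd=0.0,
                                      age_coef=0.0, missing_rate=(0.0, 0.0),
                                      seed=3)
        dw1 = (t2["weight_t1"] - t2["weight_t0"]).to_numpy()
        assert np.allclose(dw1, 0.5 * tr.propensity, atol=1e-10)

    def test_positive_coupling_detected_at_t2(self, small_atlas):
        t, _, tr = sd.simulate_cohort(
            small_atlas, sd.CohortConfig(group_sizes={"HC": 400}), seed=4)
        t2 = sd.simulate_longitudinal(t, tr, gamma=(0.5, 1.0), seed=5)
        ok = t2["weight_t2"].notna()
        dw2 = (t2.loc[ok, "weight_t2"] - t2.loc[ok, "weight_t0"]).to_numpy()
        r, p = stats.pearsonr(tr.propensity[ok.to_numpy()], dw2)
        assert r > 0 and p < 0.05

    def test_bad_missing_rate_raises(self, small_atlas):
        t, _, tr = sd.simulate_cohort(
            small_atlas, sd.CohortConfig(group_sizes={"HC": 20}), seed=4)
        with pytest.raises(sd.ConfigError):
            sd.simulate_longitudinal(t, tr, missing_rate=(1.2, 0.0), seed=0)
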