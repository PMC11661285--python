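"""Nested CV engine: assignments, evaluation oracles, leakage, significance."""

import numpy as np
import pandas as pd
import pytest

from braingap import synthdata as sd
from braingap.io import GMVMatrix
from braingap.nestedcv import (apply_ensemble, evaluate_classification,
                               evaluate_regression, make_cv,
                               permutation_significance, train_nested)
from braingap.preprocess import ChainConfig

FAST_CHAIN = ChainConfig(smooth_fwhm=0.0, pca_variance=0.8)
ONE_POINT = {"C": [1.0], "epsilon_frac": [0.1]}


def tiny_problem(seed=0, n=36, beta=0.005):
    atlas = sd.make_phantom_atlas((4, 4, 4), 2, (10, 10), 0.5, seed=seed)
    cfg = sd.CohortConfig(group_sizes={"HC": n}, beta_bmi=beta, n_sites=2)
    t, g, tr = sd.simulate_cohort(atlas, cfg, seed=seed + 1)
    return atlas, t, g, t["bmi"].to_numpy()


class TestMakeCV:
    def test_five_folds_of_two(self):
        cv = make_cv(10, k=5, r=1, seed=0)
        counts = np.bincount(cv.outer[0])
        assert np.array_equal(counts, [2, 2, 2, 2, 2])

    def test_k5_r5_yields_25_partitions(self):
        cv = make_cv(50, k=5, r=5, seed=0)
        assert cv.n_members == 25
        for rep in range(5):  # each subject in exactly one test fold per rep
            assert np.array_equal(np.sort(np.unique(cv.outer[rep])),
                                  np.arange(5))

    def test_same_seed_identical(self):
        a = make_cv(40, seed=3)
        b = make_cv(40, seed=3)
        assert np.array_equal(a.outer, b.outer)

    def test_stratified_fold_balance(self):
        y = np.array(["a"] * 30 + ["b"] * 10)
        cv = make_cv(40, k=5, r=2, seed=1, stratify=y)
        for rep in range(2):
            for f in range(5):
                sel = cv.outer[rep] == f
                assert (y[sel] == "b").sum() == 2

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError):
            make_cv(3, k=5)


class TestEvaluation:
    def test_regression_hand_oracle(self):
        pred = pd.DataFrame({"id": [1, 2, 3], "y_true": [20.0, 25.0, 30.0],
                             "ensemble": [22.0, 25.0, 28.0]})
        m = evaluate_regression(pred)
        assert np.isclose(m["MAE"], 4.0 / 3.0)
        assert np.isclose(m["R2"], 1.0 - 8.0 / 50.0)  # = 0.84
        assert np.isclose(m["r"], 1.0)

    def test_perfect_prediction(self):
        pred = pd.DataFrame({"id": [1, 2], "y_true": [20.0, 30.0],
                             "ensemble": [20.0, 30.0]})
        m = evaluate_regression(pred)
        assert m["MAE"] == 0 and m["R2"] == 1.0 and np.isclose(m["r"], 1.0)

    def test_mean_prediction_zero_r2(self):
        pred = pd.DataFrame({"id": [1, 2, 3], "y_true": [20.0, 25.0, 30.0],
                             "ensemble": [25.0, 25.0, 25.0]})
        assert np.isclose(evaluate_regression(pred)["R2"], 0.0)

    def test_zero_label_variance_rejected(self):
        pred = pd.DataFrame({"id": [1, 2], "y_true": [25.0, 25.0],
                             "ensemble": [24.0, 26.0]})
        with pytest.raises(ValueError):
            evaluate_regression(pred)

    @pytest.mark.parametrize("sens,spec,bac", [
        (0.722, 0.726, 0.724), (0.649, 0.535, 0.592)])
    def test_bac_identity(self, sens, spec, bac):
        n = 1000
        y = np.array([1] * n + [0] * n)
        yhat = np.concatenate([
            np.where(np.arange(n) < round(sens * n), 1, 0),
            np.where(np.arange(n) < round(spec * n), 0, 1)])
        pred = pd.DataFrame({"id": np.arange(2 * n), "y_true": y,
                             "ensemble": yhat})
        m = evaluate_classification(pred, positive=1)
        assert np.isclose(m["sensitivity"], sens)
        assert np.isclose(m["specificity"], spec)
        assert np.isclose(m["BAC"], bac)

    def test_all_positive_bac_half(self):
        pred = pd.DataFrame({"id": range(4), "y_true": [1, 1, 0, 0],
                             "ensemble": [1, 1, 1, 1]})
        m = evaluate_classification(pred, positive=1)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0
        assert m["BAC"] == 0.5

    def test_single_class_truth_rejected(self):
        pred = pd.DataFrame({"id": [1, 2], "y_true": [1, 1],
                             "ensemble": [1, 0]})
        with pytest.raises(ValueError):
            evaluate_classification(pred)


class TestTraining:
    def test_seeded_signal_learned(self):
        atlas, t, g, y = tiny_problem(n=120)
        cv = make_cv(120, k=5, r=2, seed=0, inner_k=3, inner_r=1)
        ens, pred = train_nested(g, t[["age", "site"]], y, cv, task="svr",
                                 grid={"C": [0.25, 1.0], "epsilon_frac": [0.1]},
                                 chain_config=FAST_CHAIN, seed=0)
        m = evaluate_regression(pred)
        assert m["R2"] > 0
        assert m["MAE"] < np.std(y)
        assert len(ens.members) == 10

    def test_shuffled_labels_no_skill(self):
        atlas, t, g, y = tiny_problem(n=100)
        rng = np.random.default_rng(5)
        y_shuf = rng.permutation(y)
        cv = make_cv(100, k=5, r=2, seed=0, inner_k=3, inner_r=1)
        ens, pred = train_nested(g, t[["age", "site"]], y_shuf, cv, task="svr",
                                 grid=ONE_POINT, chain_config=FAST_CHAIN,
                                 seed=0)
        assert evaluate_regression(pred)["R2"] <= 0.05

    def test_separable_classification_perfect_bac(self):
        """Noise-free disease effect: balanced accuracy reaches 100%."""
        atlas = sd.make_phantom_atlas((4, 4, 4), 2, (10, 10), 0.5, seed=3)
        cfg = sd.CohortConfig(group_sizes={"HC": 30, "SCZ": 30},
                              noise_sd=1e-6, age_slope_mean=0.0,
                              age_slope_sd=0.0, sex_effect_sd=0.0,
                              site_offset_sd=0.0, beta_bmi=0.0, gap_sd=0.0,
                              clinical_coupling=0.0,
                              beta_disease={"SCZ": 0.05})
        t, g, _ = sd.simulate_cohort(atlas, cfg, seed=4)
        y = t["group"].to_numpy()
        cv = make_cv(60, k=3, r=1, seed=0, stratify=y, inner_k=3, inner_r=1)
        ens, pred = train_nested(g, t[["age", "site"]], y, cv, task="svc",
                                 grid={"C": [1.0]}, chain_config=FAST_CHAIN,
                                 seed=0)
        assert evaluate_classification(pred, positive="SCZ")["BAC"] == 1.0

    def test_constant_labels_rejected(self):
        atlas, t, g, y = tiny_problem(n=30)
        cv = make_cv(30, k=3, r=1, seed=0, inner_k=3, inner_r=1)
        with pytest.raises(RuntimeError):
            train_nested(g, t[["age", "site"]], np.full(30, 25.0), cv,
                         task="svr", grid=ONE_POINT, chain_config=FAST_CHAIN)

    def test_weight_signs_recover_signature(self):
        atlas, t, g, y = tiny_problem(n=150)
        cv = make_cv(150, k=5, r=2, seed=0, inner_k=3, inner_r=1)
        ens, _ = train_nested(g, t[["age", "site"]], y, cv, task="svr",
                              grid=ONE_POINT, chain_config=FAST_CHAIN, seed=0)
        mw = ens.voxel_weight_matrix().mean(axis=0)
        assert mw[atlas.bmi_signature < 0].mean() < 0
        assert mw[atlas.bmi_signature > 0].mean() > 0


class TestLeakage:
    def test_outer_test_perturbation_changes_nothing(self):
        """Corrupting any outer-test subject's voxels leaves every fitted
        parameter of that member identical."""
        atlas, t, g, y = tiny_problem(n=30)
        cov = t[["age", "site"]]
        cv = make_cv(30, k=3, r=1, seed=0, inner_k=3, inner_r=1)
        ens1, _ = train_nested(g, cov, y, cv, task="svr", grid=ONE_POINT,
                               chain_config=FAST_CHAIN, seed=0)
        for member in ens1.members:
            test_subject = np.flatnonzero(cv.outer[member.rep] == member.fold)[0]
            g2 = GMVMatrix(g.data.copy(), g.grid_shape)
            g2.data[test_subject] += 50.0
            ens2, _ = train_nested(g2, cov, y, cv, task="svr", grid=ONE_POINT,
                                   chain_config=FAST_CHAIN, seed=0)
            m2 = [m for m in ens2.members
                  if (m.rep, m.fold) == (member.rep, member.fold)][0]
            assert np.array_equal(member.coef, m2.coef)
            assert member.intercept == m2.intercept
            assert np.array_equal(member.chain.components, m2.chain.components)
            assert np.array_equal(member.chain.age_slopes, m2.chain.age_slopes)
            assert member.params == m2.params


class TestPermutation:
    def test_p_lower_bound_and_strong_signal(self):
        atlas, t, g, y = tiny_problem(n=60, beta=0.02)
        cv = make_cv(60, k=3, r=1, seed=0, inner_k=3, inner_r=1)
        res = permutation_significance(g, t[["age", "site"]], y, cv,
                                       task="svr", grid=ONE_POINT,
                                       chain_config=FAST_CHAIN, n_perm=19,
                                       seed=0)
        assert res.p >= 1.0 / 20.0
        assert res.p == 1.0 / 20.0  # strong seeded signal beats every perm

    def test_n_perm_floor(self):
        atlas, t, g, y = tiny_problem(n=30)
        cv = make_cv(30, k=3, r=1, seed=0, inner_k=3, inner_r=1)
        with pytest.raises(ValueError):
            permutation_significance(g, t[["age", "site"]], y, cv,
                                     n_perm=5, chain_config=FAST_CHAIN)


class TestApplyEnsemble:
    @pytest.fixture(scope="class")
    @staticmethod
    def trained():
        atlas, t, g, y = tiny_problem(n=60)
        cv = make_cv(60, k=3, r=2, seed=0, inner_k=3, inner_r=1)
        ens, pred = train_nested(g, t[["age", "site"]], y, cv, task="svr",
                                 grid=ONE_POINT, chain_config=FAST_CHAIN,
                                 seed=0)
        return atlas, t, g, y, ens, pred

    def test_duplicate_rows_identical_predictions(self, trained):
        atlas, t, g, y, ens, _ = trained
        dup = GMVMatrix(np.vstack([g.data[:1], g.data[:1]]), g.grid_shape)
        cov = pd.concat([t[["age", "site"]].iloc[:1]] * 2, ignore_index=True)
        out = apply_ensemble(ens, dup, cov)
        assert out["ensemble"][0] == out["ensemble"][1]

    def test_training_cohort_application_finite(self, trained):
        atlas, t, g, y, ens, pred = trained
        out = apply_ensemble(ens, g, t[["age", "site"]])
        assert np.isfinite(out["ensemble"]).all()
        # in-fold application differs from out-of-fold CV predictions
        assert not np.allclose(out["ensemble"], pred["ensemble"])

    def test_voxel_mismatch_rejected(self, trained):
        atlas, t, g, y, ens, _ = trained
        bad = GMVMatrix(np.zeros((2, 10)), None)
        with pytest.raises(ValueError):
            apply_ensemble(ens, bad, t[["age", "site"]].iloc[:2])
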