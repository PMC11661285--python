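"""Config-driven end-to-end runs on phantom cohorts.

``run_pipeline`` executes the analysis stages in dependency order —
simulate -> cohort -> train -> gap -> maps -> spls -> longitudinal — from a
single :class:`RunConfig`, returning all in-memory artifacts and (when an
output directory is given) writing each artifact with a JSON manifest
recording the stage inputs, config hash and seed, so every number in every
report is recomputable from the logged configuration alone.

A single global seed is expanded into independent per-stage substreams by
hashing the stage name into the seed sequence, so individual stages are
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import gap as gap_mod
from . import longitudinal as long_mod
from . import maps as maps_mod
from . import spls as spls_mod
from . import synthdata
from .io import GMVMatrix, write_gmv, write_table
from .nestedcv import (apply_ensemble, build_feature_cache,
                       evaluate_classification, evaluate_regression, make_cv,
                       permutation_significance, train_nested)
from .preprocess import ChainConfig

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "STAGES"]

STAGES = ("simulate", "cohort", "train", "gap", "maps", "spls", "longitudinal")

CLINICAL_FEATURES = ("bmigap", "scz_expression", "panss_total",
                     "age_of_onset", "illness_duration", "hospitalizations")


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage substream: the stage name is hashed into the seed sequence."""
    return int(np.random.SeedSequence(
        (int(global_seed), zlib.crc32(stage.encode()))).generate_state(1)[0]
        % (2 ** 31))


@dataclass
class RunConfig:
    """Serializable configuration of a full phantom-study run."""

    seed: int = 0
    # atlas / generator
    grid_shape: tuple = (12, 12, 12)
    n_regions: int = 8
    signature_sizes: tuple = (60, 60)
    overlap_fraction: float = 0.5
    group_sizes: dict = field(default_factory=lambda: {
        "HC": 500, "SCZ": 120, "CHR": 150, "ROD": 150})
    cohort_overrides: dict = field(default_factory=dict)
    # discovery sampling
    bin_lo: float = 18.5
    bin_hi: float = 35.0
    bin_width: float = 0.5
    discovery_n: int = 250
    # preprocessing + CV
    # smoothing off by default: voxel-map recovery is scored against the
    # exact seeded support, which kernel smoothing deliberately blurs
    chain: dict = field(default_factory=lambda: {
        "smooth_fwhm": 0.0, "pca_variance": 0.8})
    outer_k: int = 5
    outer_r: int = 5
    inner_k: int = 5
    inner_r: int = 2
    grid: dict = field(default_factory=lambda: {
        "C": [0.25, 1.0, 4.0], "epsilon_frac": [0.1]})
    n_perm_model: int = 0  # label permutations for model significance (0 = skip)
    # maps
    q_threshold: float = 0.05
    # spls
    spls_n_perm: int = 199
    spls_max_lv: int = 5
    spls_c_u: float | None = None
    spls_c_v: float | None = None
    # longitudinal
    gamma: tuple = (0.5, 1.0)
    # mean follow-up weight gain per patient group (kg): clinical cohorts in
    # early illness gain weight on average, which also sets a realistic
    # prevalence for the +7% gain label
    weight_group_offsets: dict = field(default_factory=lambda: {
        "SCZ": 2.0, "CHR": 2.0, "ROD": 2.0})
    wg_threshold_pct: float = 7.0
    wg_horizon: int = 2
    wg_ablation_n_perm: int = 2000

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, cfg: RunConfig, extra: dict):
    manifest = {"stage": stage, "config_hash": cfg.digest(),
                "seed": cfg.seed, "stage_seed": stage_seed(cfg.seed, stage),
                **extra}
    (outdir / f"{stage}_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))


def run_pipeline(config: RunConfig, stages=None, out: str | Path | None = None
                 ) -> dict:
    """Run the requested stages (all by default) and return artifacts.

    Later stages pull their inputs from the artifact dict; requesting a
    stage without its upstream artifacts raises a dependency error naming
    the missing stage.
    """
    cfg = config
    stages = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    outdir = None
    if out is not None:
        outdir = Path(out)
        outdir.mkdir(parents=True, exist_ok=True)
    art: dict = {"config": cfg}

    def need(key: str, producer: str):
        if key not in art:
            raise RuntimeError(
                f"missing upstream artifact {key!r}: run stage {producer!r} first")
        return art[key]

    for stage in stages:
        s_seed = stage_seed(cfg.seed, stage)
        log.info("stage %s (seed %d)", stage, s_seed)
        if stage == "simulate":
            atlas = synthdata.make_phantom_atlas(
                cfg.grid_shape, cfg.n_regions, cfg.signature_sizes,
                cfg.overlap_fraction, seed=s_seed)
            ccfg = synthdata.CohortConfig(group_sizes=dict(cfg.group_sizes),
                                          **cfg.cohort_overrides)
            subjects, gmv, truth = synthdata.simulate_cohort(atlas, ccfg,
                                                             seed=s_seed + 1)
            subjects = synthdata.simulate_longitudinal(
                subjects, truth, gamma=tuple(cfg.gamma),
                group_offsets=dict(cfg.weight_group_offsets), seed=s_seed + 2)
            art.update(atlas=atlas, subjects=subjects, gmv=gmv, truth=truth,
                       cohort_config=ccfg)
            if outdir:
                write_table(subjects, outdir / "subjects.csv")
                write_gmv(gmv, outdir / "gmv")
                _write_manifest(outdir, stage, cfg,
                                {"n_subjects": len(subjects)})
        elif stage == "cohort":
            subjects = need("subjects", "simulate")
            included, excl = cohort_mod.apply_inclusion(subjects)
            hc = included[included["group"] == "HC"].reset_index(drop=True)
            spec = cohort_mod.BinSpec(cfg.bin_lo, cfg.bin_hi, cfg.bin_width)
            split = cohort_mod.sample_uniform_with_matching(
                hc, spec, min(cfg.discovery_n, len(hc)), seed=s_seed)
            art.update(included=included, exclusions=excl, hc=hc,
                       binspec=spec, split=split)
            if outdir:
                write_table(split.table, outdir / "split.csv")
                _write_manifest(outdir, stage, cfg, {
                    "n_included": len(included),
                    "n_discovery": int((split.table["partition"] == "discovery").sum())})
        elif stage == "train":
            subjects = need("subjects", "simulate")
            gmv: GMVMatrix = need("gmv", "simulate")
            split = need("split", "cohort")
            chain = ChainConfig(**cfg.chain)
            disc_ids = set(split.ids("discovery"))
            idx = {sid: i for i, sid in enumerate(subjects["id"])}
            disc_idx = np.array(sorted(idx[i] for i in disc_ids))
            cov = subjects[["age", "site"]]
            y_bmi = subjects["bmi"].to_numpy()
            cv = make_cv(disc_idx.size, cfg.outer_k, cfg.outer_r,
                         seed=s_seed, inner_k=cfg.inner_k, inner_r=cfg.inner_r)
            cache = build_feature_cache(gmv.select(disc_idx),
                                        cov.iloc[disc_idx].reset_index(drop=True),
                                        cv, chain)
            bmi_ens, bmi_pred = train_nested(
                gmv.select(disc_idx), cov.iloc[disc_idx].reset_index(drop=True),
                y_bmi[disc_idx], cv, task="svr", grid=cfg.grid,
                chain_config=chain, seed=s_seed, cache=cache)
            bmi_metrics = evaluate_regression(bmi_pred)
            art.update(bmi_ensemble=bmi_ens, bmi_pred=bmi_pred,
                       bmi_metrics=bmi_metrics, discovery_idx=disc_idx,
                       chain_config=chain, bmi_cv=cv)
            if cfg.n_perm_model:
                art["bmi_perm"] = permutation_significance(
                    gmv.select(disc_idx), cov.iloc[disc_idx].reset_index(drop=True),
                    y_bmi[disc_idx], cv, task="svr", grid=cfg.grid,
                    chain_config=chain, n_perm=cfg.n_perm_model,
                    seed=s_seed, cache=cache)
            # SCZ-vs-HC(discovery) classifier with the same settings
            scz_idx = np.flatnonzero(subjects["group"].to_numpy() == "SCZ")
            if scz_idx.size:
                clf_idx = np.concatenate([disc_idx, scz_idx])
                y_dx = subjects["group"].to_numpy()[clf_idx]
                y_dx = np.where(y_dx == "SCZ", "SCZ", "HC")
                cv_dx = make_cv(clf_idx.size, cfg.outer_k, cfg.outer_r,
                                seed=s_seed + 1, stratify=y_dx,
                                inner_k=cfg.inner_k, inner_r=cfg.inner_r)
                dx_grid = {"C": cfg.grid.get("C", [1.0])}
                dx_ens, dx_pred = train_nested(
                    gmv.select(clf_idx), cov.iloc[clf_idx].reset_index(drop=True),
                    y_dx, cv_dx, task="svc", grid=dx_grid,
                    chain_config=chain, seed=s_seed + 1)
                art.update(dx_ensemble=dx_ens, dx_pred=dx_pred,
                           dx_idx=clf_idx,
                           dx_metrics=evaluate_classification(dx_pred,
                                                              positive="SCZ"))
            if outdir:
                write_table(bmi_pred, outdir / "bmi_predictions.csv")
                _write_manifest(outdir, stage, cfg, {"bmi_metrics": bmi_metrics})
        elif stage == "gap":
            subjects = need("subjects", "simulate")
            gmv = need("gmv", "simulate")
            bmi_ens = need("bmi_ensemble", "train")
            bmi_pred = need("bmi_pred", "train")
            disc_idx = art["discovery_idx"]
            cov = subjects[["age", "site"]]
            # fit correction on discovery out-of-fold predictions
            raw_disc = gap_mod.compute_gap(bmi_pred["ensemble"],
                                           bmi_pred["y_true"])
            corr = gap_mod.fit_gap_correction(
                raw_disc, bmi_pred["y_true"], cohort_id="HC_discovery")
            # apply the frozen model + correction to everyone else
            rest = np.setdiff1d(np.arange(len(subjects)), disc_idx)
            applied = apply_ensemble(bmi_ens, gmv.select(rest),
                                     cov.iloc[rest].reset_index(drop=True))
            sub_rest = subjects.iloc[rest]
            group = np.where(sub_rest["group"] == "HC", "HC_validation",
                             sub_rest["group"])
            gt_rest = gap_mod.make_gap_table(sub_rest["id"], group,
                                             sub_rest["bmi"].to_numpy(),
                                             applied["ensemble"].to_numpy(), corr)
            gt_disc = gap_mod.make_gap_table(
                bmi_pred["id"], np.repeat("HC_discovery", len(bmi_pred)),
                bmi_pred["y_true"].to_numpy(), bmi_pred["ensemble"].to_numpy(),
                corr)
            gap_table = pd.concat([gt_disc, gt_rest], ignore_index=True)
            art.update(gap_correction=corr, gap_table=gap_table,
                       gap_summary=gap_mod.summarize_gap_by_group(gap_table),
                       applied_pred=applied)
            if outdir:
                write_table(gap_table, outdir / "gap_table.csv")
                write_table(art["gap_summary"], outdir / "gap_summary.csv")
                _write_manifest(outdir, stage, cfg, {
                    "correction": dataclasses.asdict(corr)})
        elif stage == "maps":
            bmi_ens = need("bmi_ensemble", "train")
            W = bmi_ens.voxel_weight_matrix()
            bmi_cons = maps_mod.sign_consistency_map(W, cfg.grid_shape)
            bmi_mask = maps_mod.binarize_map(bmi_cons, cfg.q_threshold)
            art.update(bmi_consistency=bmi_cons, bmi_mask=bmi_mask,
                       bmi_cvr=maps_mod.cvr_map(W, cfg.grid_shape))
            if "dx_ensemble" in art:
                Wd = art["dx_ensemble"].voxel_weight_matrix()
                dx_cons = maps_mod.sign_consistency_map(Wd, cfg.grid_shape)
                dx_mask = maps_mod.binarize_map(dx_cons, cfg.q_threshold)
                overlap = maps_mod.overlap_masks(bmi_mask, dx_mask,
                                                 bmi_cons, dx_cons,
                                                 cfg.q_threshold, cfg.q_threshold)
                art.update(dx_consistency=dx_cons, dx_mask=dx_mask,
                           overlap=overlap)
            if outdir:
                write_table(bmi_cons.to_frame(), outdir / "bmi_consistency.csv")
                _write_manifest(outdir, stage, cfg, {
                    "bmi_mask_voxels": int(bmi_mask.sum()),
                    "overlap_voxels": int(art["overlap"].n_voxels)
                    if "overlap" in art else None})
        elif stage == "spls":
            subjects = need("subjects", "simulate")
            gmv = need("gmv", "simulate")
            gap_table = need("gap_table", "gap")
            overlap = need("overlap", "maps")
            dx_ens = need("dx_ensemble", "train")
            scz = subjects[subjects["group"] == "SCZ"]
            if overlap.n_voxels < 2 or len(scz) < 10:
                log.warning("spls skipped: overlap %d voxels, %d SCZ subjects",
                            overlap.n_voxels, len(scz))
                art["spls_model"] = None
                continue
            scz_idx = scz.index.to_numpy()
            cov = subjects[["age", "site"]]
            expr = apply_ensemble(dx_ens, gmv.select(scz_idx),
                                  cov.iloc[scz_idx].reset_index(drop=True))
            gmap = gap_table.set_index("id")
            X = np.column_stack([
                gmap.loc[scz["id"], "gap_corrected"].to_numpy(),
                expr["decision_score"].to_numpy(),
                scz["panss_total"].to_numpy(),
                scz["age_of_onset"].to_numpy(),
                scz["illness_duration"].to_numpy(),
                scz["hospitalizations"].to_numpy(),
            ])
            Y = gmv.data[scz_idx][:, overlap.mask]
            scfg = spls_mod.SPLSConfig(c_u=cfg.spls_c_u, c_v=cfg.spls_c_v,
                                       n_perm=cfg.spls_n_perm,
                                       max_lv=cfg.spls_max_lv)
            model = spls_mod.fit_spls(spls_mod.standardize_columns(X),
                                      spls_mod.standardize_columns(Y),
                                      scfg, seed=s_seed,
                                      feature_names=list(CLINICAL_FEATURES))
            art["spls_model"] = model
            if outdir:
                _write_manifest(outdir, stage, cfg, {
                    "n_lv": model.n_significant,
                    "rho": [lv.rho for lv in model.lvs]})
        elif stage == "longitudinal":
            subjects = need("subjects", "simulate")
            gap_table = need("gap_table", "gap")
            wc = long_mod.compute_weight_change(subjects)
            scan = long_mod.subgroup_correlation_scan(
                gap_table, wc, subjects=subjects)
            pat = subjects[subjects["group"].isin(["CHR", "ROD"])]
            wc_pat = wc[wc["id"].isin(pat["id"])].reset_index(drop=True)
            labels = long_mod.weight_gain_labels(wc_pat, cfg.wg_threshold_pct,
                                                 cfg.wg_horizon)
            art.update(weight_change=wc, scan=scan)
            if labels.size >= 20 and np.unique(labels).size == 2:
                gmap = gap_table.set_index("id")
                feat = pd.DataFrame({
                    "bmigap": gmap.loc[pat["id"], "gap_corrected"].to_numpy(),
                    "age": pat["age"].to_numpy(),
                    "sex": (pat["sex"] == "F").astype(int).to_numpy(),
                    "group_rod": (pat["group"] == "ROD").astype(int).to_numpy(),
                    "exercise": pat["exercise"].to_numpy(),
                    "somatic_history": pat["somatic_history"].to_numpy(),
                    "tobacco": pat["tobacco"].to_numpy(),
                }, index=pat["id"])
                rep_with = long_mod.predict_weight_gain(
                    feat, labels, k=cfg.outer_k, r=cfg.outer_r, seed=s_seed)
                rep_wo = long_mod.predict_weight_gain(
                    feat.drop(columns=["bmigap"]), labels, cv=rep_with.cv,
                    seed=s_seed)
                art.update(wg_with=rep_with, wg_without=rep_wo,
                           wg_ablation=long_mod.ablation_compare(
                               rep_with, rep_wo, cfg.wg_ablation_n_perm,
                               seed=s_seed))
            else:
                log.warning("weight-gain classifier skipped (labels degenerate)")
            if outdir:
                write_table(scan, outdir / "correlation_scan.csv")
                _write_manifest(outdir, stage, cfg, {
                    "wg_bac": art["wg_with"].bac if "wg_with" in art else None})
    return art
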