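"""End-to-end retrospective / prospective readmission-risk experiment.

One run config drives every stage: simulate the cohort, aggregate look-back
features, assign sub-cohorts and the facility-balanced split, fit the four
sub-cohort survival forests on subgroup-1 training rows, calibrate the 0-100
PPV score on subgroup-1 calibration rows, blind-test on subgroup-2
facilities, then score the temporally later prospective phase and cluster its
high-risk encounters.  All randomness flows from the single run seed through
named substreams; rerunning a config reproduces every artifact byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import calibration as calib_mod
from . import clustering as clus_mod
from . import evaluation as eval_mod
from .cohort import (
    CohortSplit,
    aggregate_features,
    assign_subcohort,
    facility_balanced_split,
    variance_filter,
)
from .forest import (
    ForestConfig,
    SurvivalForest,
    SurvivalForestResults,
    forward_feature_selection,
)
from .synthetic_ehr import GeneratorConfig, generate_cohort, write_cohort

logger = logging.getLogger("readmit_rsf.pipeline")

SUBCOHORT_KEY = "subcohorts"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_run_config() -> dict:
    """Desk-scale defaults for the full experiment.

    10,000 index discharges over 24 months; retrospective phase = months
    13-18, prospective = months 19-24; 50 variance-filtered features;
    100-tree forests per sub-cohort; 30/70 tier cuts; clustering elbow
    threshold 0.2.
    """
    return {
        "seed": 0,
        "generator": {},  # GeneratorConfig field overrides
        "cohort": {
            "lookback_days": 365,
            "n_keep": 50,
            "train_fraction": 0.7,
            "prospective_from_month": 18,  # months after calendar start
        },
        "forest": {
            "ntree": 100,
            "mtry": None,
            "nodesize_min": 3,
            "horizon_days": 30,
        },
        "selection": {
            "enabled": False,
            "batch_size": 5,
            "tol": 1e-3,
            "patience": 2,
            "n_start": 10,
            "ntree": 50,
        },
        "calibration": {"low": 30.0, "high": 70.0},
        "clustering": {"k_max": 10, "threshold": 0.2, "n_restarts": 10},
    }


def load_run_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file and an override dict."""
    cfg = default_run_config()
    layers = []
    if path is not None:
        with open(path) as fh:
            layers.append(yaml.safe_load(fh) or {})
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for key, val in layer.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


@dataclass
class RunManifest:
    """Per-stage artifact paths, checksums, timings and seed substreams."""

    stages: dict = field(default_factory=dict)

    def record(self, stage: str, artifacts: dict, wall_time: float,
               seed) -> None:
        self.stages[stage] = {
            "artifacts": {
                name: {"path": p, "sha256": _sha256(p)}
                for name, p in artifacts.items()},
            "wall_time_s": round(wall_time, 3),
            "seed_substream": seed,
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.stages, fh, indent=1, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ----------------------------------------------------------------- stages


def generator_config(config: dict) -> GeneratorConfig:
    return GeneratorConfig(seed=config["seed"], **config["generator"])


def prospective_start(config: dict) -> pd.Timestamp:
    gen = generator_config(config)
    months = config["cohort"]["prospective_from_month"]
    return pd.Timestamp(gen.start_date) + pd.DateOffset(months=months)


def build_features(patients, encounters, index, config: dict) -> pd.DataFrame:
    return aggregate_features(
        patients, encounters, index,
        lookback_days=config["cohort"]["lookback_days"])


def build_split(patients, index, config: dict) -> CohortSplit:
    merged = index.merge(patients[["patient_id", "facility_id"]],
                         on="patient_id", how="left")
    return facility_balanced_split(
        merged,
        seed=config["seed"],
        train_fraction=config["cohort"]["train_fraction"],
        prospective_start=prospective_start(config))


def _forest_config(config: dict, subcohort_seed: int,
                   ntree: int | None = None) -> ForestConfig:
    f = config["forest"]
    return ForestConfig(
        ntree=ntree or f["ntree"], mtry=f["mtry"],
        nodesize_min=f["nodesize_min"], seed=subcohort_seed,
        horizon_days=f["horizon_days"])


def _youden_at_high(results, cal_map, X_cal, y_cal, high: float) -> float:
    score = cal_map.score(results.predict_risk(X_cal))
    pred = score >= high
    pos, neg = y_cal == 1, y_cal == 0
    if pos.sum() == 0 or neg.sum() == 0:
        return 0.0
    sens = float(pred[pos].mean())
    spec = float((~pred[neg]).mean())
    return sens + spec - 1.0


def fit_subcohort_models(features: pd.DataFrame, index: pd.DataFrame,
                         split: CohortSplit, subcohorts: pd.Series,
                         kept: list[str], config: dict):
    """Fit and calibrate one survival forest per sub-cohort.

    Returns (results_by_subcohort, maps_by_subcohort, features_by_subcohort).
    When the selection stage is enabled, a permutation-importance ranking from
    the full-feature fit seeds an iterative forward selection scored by
    sensitivity + specificity - 1 at the high-tier threshold on the
    calibration rows, and the final model is refit on the winning set.
    """
    idx = index.set_index("index_id")
    train_ids = split.ids("train")
    cal_ids = split.ids("calibration")
    sel_cfg = config["selection"]
    high = config["calibration"]["high"]
    results_by, maps_by, feats_by = {}, {}, {}
    for si, label in enumerate(sorted(subcohorts.unique())):
        ids_tr = train_ids[subcohorts.loc[train_ids] == label]
        ids_ca = cal_ids[subcohorts.loc[cal_ids] == label]
        if len(ids_tr) == 0 or len(ids_ca) == 0:
            raise PipelineError(
                "fit", ValueError(
                    f"sub-cohort {label!r} has no train or calibration rows"))
        sub_seed = config["seed"] * 8 + si  # distinct stream per sub-cohort
        X_tr = features.loc[ids_tr, kept]
        t_tr = idx.loc[ids_tr, "observed_time"]
        e_tr = idx.loc[ids_tr, "event_observed"].astype(int)
        X_ca = features.loc[ids_ca, kept]
        y_ca = idx.loc[ids_ca, "event_within_30d"].astype(int).to_numpy()

        fc = _forest_config(config, sub_seed)
        res = SurvivalForest(t_tr, e_tr, X_tr, config=fc).fit()
        feat_set = list(kept)

        if sel_cfg["enabled"] and len(kept) > sel_cfg["n_start"]:
            imp = res.permutation_importance(X_ca, y_ca, seed=sub_seed)

            def eval_fn(subset: list[str]) -> float:
                fc_s = _forest_config(config, sub_seed,
                                      ntree=sel_cfg["ntree"])
                r = SurvivalForest(t_tr, e_tr, X_tr[subset],
                                   config=fc_s).fit()
                m = calib_mod.fit_calibration(
                    r.predict_risk(X_ca[subset]), y_ca, subcohort=label)
                return _youden_at_high(r, m, X_ca[subset], y_ca, high)

            feat_set = forward_feature_selection(
                imp, eval_fn,
                batch_size=sel_cfg["batch_size"], tol=sel_cfg["tol"],
                patience=sel_cfg["patience"], n_start=sel_cfg["n_start"])
            res = SurvivalForest(t_tr, e_tr, X_tr[feat_set],
                                 config=fc).fit()
            X_ca = X_ca[feat_set]

        cal_map = calib_mod.fit_calibration(
            res.predict_risk(X_ca), y_ca, subcohort=label)
        results_by[label] = res
        maps_by[label] = cal_map
        feats_by[label] = feat_set
        logger.info("fitted sub-cohort %s: n_train=%d n_cal=%d p=%d",
                    label, len(ids_tr), len(ids_ca), len(feat_set))
    return results_by, maps_by, feats_by


def score_rows(results_by, maps_by, feats_by, features, subcohorts,
               ids, config: dict) -> pd.DataFrame:
    """Unified 0-100 scores for the given index ids."""
    cal = config["calibration"]
    sub = subcohorts.loc[ids]
    rows = []
    for label, res in results_by.items():
        mask_ids = sub.index[sub == label]
        if len(mask_ids) == 0:
            continue
        X = features.loc[mask_ids, feats_by[label]]
        h30 = res.predict_risk(X)
        score = maps_by[label].score(h30)
        rows.append(pd.DataFrame({
            "index_id": mask_ids, "subcohort": label, "H30": h30,
            "score": score,
            "tier": calib_mod.assign_tiers(score, cal["low"], cal["high"]),
        }))
    unknown = set(sub.unique()) - set(results_by)
    if unknown:
        raise ValueError(f"no fitted model for sub-cohorts {sorted(unknown)}")
    if not rows:
        return pd.DataFrame(
            columns=["index_id", "subcohort", "H30", "score", "tier"])
    out = pd.concat(rows, ignore_index=True)
    return out.set_index("index_id").loc[ids].reset_index()


def evaluate_scores(scores: pd.DataFrame, index: pd.DataFrame,
                    config: dict) -> dict:
    """Evaluation report: bin/tier rates, c-statistic, per-tier KM curves."""
    idx = index.set_index("index_id")
    joined = scores.set_index("index_id").join(
        idx[["event_within_30d", "observed_time", "event_observed"]],
        how="left")
    y = joined["event_within_30d"].astype(int).to_numpy()
    s = joined["score"].to_numpy()
    bins, tiers = eval_mod.bin_rates(s, y)
    report = {
        "n": int(len(joined)),
        "event_rate": float(y.mean()) if len(joined) else None,
        "bins": [vars(b) for b in bins],
        "tiers": tiers,
        "tier_thresholds": {"low": config["calibration"]["low"],
                            "high": config["calibration"]["high"]},
        "auc": None,
        "km": {},
        "median_days": {},
    }
    if len(joined) and 0 < y.sum() < len(y):
        report["auc"] = eval_mod.c_statistic(s, y).auc
    for tier in ("Low", "Intermediate", "High"):
        mask = joined["tier"] == tier
        if not mask.any():
            continue
        curve = eval_mod.km_curve(
            joined.loc[mask, "observed_time"],
            joined.loc[mask, "event_observed"].astype(int), tier=tier)
        report["km"][tier] = curve.survival.tolist()
        med = eval_mod.median_time_to_event(curve)
        report["median_days"][tier] = med
    return report


# ------------------------------------------------------------- run stages


def _dump_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True)


def run_retrospective(config: dict, outdir: str,
                      tables=None) -> RunManifest:
    """Simulate (unless tables are given), build, fit, calibrate, blind-test.

    Writes cohort CSVs, features.csv, split.json, model.json,
    scores_retrospective.csv and evaluation_retrospective.json under
    ``outdir`` and returns the manifest.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest()
    t0 = time.time()
    stage = "simulate"
    try:
        if tables is None:
            tables = generate_cohort(generator_config(config))
        patients, encounters, index = tables
        files = write_cohort(tables, os.path.join(outdir, "cohort"))
        manifest.record(stage, files, time.time() - t0, config["seed"])

        stage = "build"
        t0 = time.time()
        features = build_features(patients, encounters, index, config)
        split = build_split(patients, index, config)
        subcohorts = assign_subcohort(features)
        retro_fit_ids = split.assignment.index[
            split.assignment.isin(["train", "calibration"])]
        kept = variance_filter(features.loc[retro_fit_ids],
                               config["cohort"]["n_keep"])
        fpath = os.path.join(outdir, "features.csv")
        features.to_csv(fpath)
        spath = os.path.join(outdir, "split.json")
        _dump_json({"assignment": split.assignment.to_dict(),
                    "facility_partition": split.facility_partition,
                    "kept_features": kept,
                    "subcohorts": subcohorts.to_dict()}, spath)
        manifest.record(stage, {"features": fpath, "split": spath},
                        time.time() - t0, config["seed"])

        stage = "fit"
        t0 = time.time()
        results_by, maps_by, feats_by = fit_subcohort_models(
            features, index, split, subcohorts, kept, config)
        mpath = os.path.join(outdir, "model.json")
        _dump_json({
            SUBCOHORT_KEY: {
                label: {"forest": results_by[label].to_dict(),
                        "calibration": maps_by[label].to_dict(),
                        "features": feats_by[label]}
                for label in results_by},
            "config": copy.deepcopy(config),
        }, mpath)
        manifest.record(stage, {"model": mpath}, time.time() - t0,
                        config["seed"])

        stage = "blind_test"
        t0 = time.time()
        blind_ids = split.ids("blind_test")
        scores = score_rows(results_by, maps_by, feats_by, features,
                            subcohorts, blind_ids, config)
        scpath = os.path.join(outdir, "scores_retrospective.csv")
        scores.to_csv(scpath, index=False)
        report = evaluate_scores(scores, index, config)
        epath = os.path.join(outdir, "evaluation_retrospective.json")
        _dump_json(report, epath)
        manifest.record(stage, {"scores": scpath, "evaluation": epath},
                        time.time() - t0, config["seed"])
    except PipelineError:
        logger.exception("stage failed")
        raise
    except Exception as exc:
        logger.exception("stage %s failed", stage)
        raise PipelineError(stage, exc) from exc
    manifest.save(os.path.join(outdir, "manifest_retrospective.json"))
    return manifest


def _load_models(model_path: str):
    with open(model_path) as fh:
        doc = json.load(fh)
    results_by, maps_by, feats_by = {}, {}, {}
    for label, entry in doc[SUBCOHORT_KEY].items():
        results_by[label] = SurvivalForestResults.from_dict(entry["forest"])
        maps_by[label] = calib_mod.CalibrationMap.from_dict(
            entry["calibration"])
        feats_by[label] = entry["features"]
    return results_by, maps_by, feats_by, doc.get("config", {})


def run_prospective(config: dict, model_path: str, outdir: str,
                    tables=None) -> RunManifest:
    """Score the prospective phase with fitted models; cluster high-risk rows.

    Writes scores_prospective.csv, evaluation_prospective.json and -- when
    high-risk encounters exist -- clusters.csv, cluster_profiles.json and
    selection_trace.csv.  An empty prospective cohort yields a zero-row report
    and a warning, not an error.
    """
    if not os.path.exists(model_path):
        raise FileNotFoundError(f"model file not found: {model_path}")
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest()
    stage = "score_prospective"
    t0 = time.time()
    try:
        results_by, maps_by, feats_by, _ = _load_models(model_path)
        if tables is None:
            tables = generate_cohort(generator_config(config))
        patients, encounters, index = tables
        features = build_features(patients, encounters, index, config)
        subcohorts = assign_subcohort(features)
        start = prospective_start(config)
        prosp_ids = index.loc[
            index["discharge_date"] >= start, "index_id"]
        prosp_ids = pd.Index(prosp_ids)
        if len(prosp_ids) == 0:
            warnings.warn("prospective cohort is empty; nothing to score",
                          stacklevel=2)
            scores = pd.DataFrame(
                columns=["index_id", "subcohort", "H30", "score", "tier"])
        else:
            scores = score_rows(results_by, maps_by, feats_by, features,
                                subcohorts, prosp_ids, config)
        scpath = os.path.join(outdir, "scores_prospective.csv")
        scores.to_csv(scpath, index=False)
        report = evaluate_scores(scores, index, config)
        epath = os.path.join(outdir, "evaluation_prospective.json")
        _dump_json(report, epath)
        manifest.record(stage, {"scores": scpath, "evaluation": epath},
                        time.time() - t0, config["seed"])

        stage = "cluster"
        t0 = time.time()
        high_ids = pd.Index(scores.loc[scores["tier"] == "High", "index_id"])
        artifacts = {}
        if len(high_ids) >= 3:
            cluster_feats = sorted(set().union(*feats_by.values()))
            cl_cfg = config["clustering"]
            proj = clus_mod.pca_project(features.loc[high_ids, cluster_feats])
            sel = clus_mod.select_k(
                proj.coords.to_numpy(),
                k_max=min(cl_cfg["k_max"], len(high_ids)),
                threshold=cl_cfg["threshold"],
                n_restarts=cl_cfg["n_restarts"], seed=config["seed"])
            labels, twss, _ = clus_mod.kmeans_twss(
                proj.coords.to_numpy(), sel.k_selected,
                n_restarts=cl_cfg["n_restarts"], seed=config["seed"])
            cdf = proj.coords.copy()
            cdf.insert(0, "cluster_id", labels)
            cpath = os.path.join(outdir, "clusters.csv")
            cdf.to_csv(cpath)
            profiles = clus_mod.profile_clusters(
                labels, features.loc[high_ids], coords=proj.coords)
            ppath = os.path.join(outdir, "cluster_profiles.json")
            _dump_json({"k_selected": sel.k_selected, "k_peak": sel.k_peak,
                        "twss_at_k": twss, "profiles": profiles}, ppath)
            tpath = os.path.join(outdir, "selection_trace.csv")
            sel.trace().to_csv(tpath, index=False)
            artifacts = {"clusters": cpath, "profiles": ppath,
                         "trace": tpath}
        else:
            warnings.warn(
                f"only {len(high_ids)} high-risk encounters; clustering "
                "skipped", stacklevel=2)
        manifest.record(stage, artifacts, time.time() - t0, config["seed"])
    except PipelineError:
        raise
    except FileNotFoundError:
        raise
    except Exception as exc:
        logger.exception("stage %s failed", stage)
        raise PipelineError(stage, exc) from exc
    manifest.save(os.path.join(outdir, "manifest_prospective.json"))
    return manifest


def run_all(config: dict, outdir: str, tables=None) -> RunManifest:
    """Full experiment: retrospective modelling then prospective validation.

    Also writes the combined scores.csv (blind-test + prospective rows on the
    unified 0-100 scale).
    """
    if tables is None:
        tables = generate_cohort(generator_config(config))
    m1 = run_retrospective(config, outdir, tables=tables)
    m2 = run_prospective(config, os.path.join(outdir, "model.json"), outdir,
                         tables=tables)
    retro = pd.read_csv(os.path.join(outdir, "scores_retrospective.csv"))
    prosp = pd.read_csv(os.path.join(outdir, "scores_prospective.csv"))
    retro["phase"] = "retrospective_blind"
    prosp["phase"] = "prospective"
    combined = pd.concat([retro, prosp], ignore_index=True)
    combined.to_csv(os.path.join(outdir, "scores.csv"), index=False)
    manifest = RunManifest(stages={**m1.stages, **m2.stages})
    manifest.save(os.path.join(outdir, "manifest.json"))
    return manifest
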