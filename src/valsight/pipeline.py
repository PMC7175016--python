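"""Pipeline orchestration: simulate -> fit-q -> deconvolve -> decode.

Each stage reads the previous stage's artifacts from the output
directory, derives its own seed from the global seed, and records what it
wrote in a manifest. Re-running with the same configuration and seed
reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import fir, forest, hierarchical, io, qlearning, signals, simulate, task

log = logging.getLogger("valsight")

STAGES = ("simulate", "fit-q", "deconvolve", "decode")

DEFAULT_CONFIG = {
    "task": {},
    "cohort": {"n_subjects": 12, "mu_z": None, "sigma_z": None},
    "signal": {},
    "qlearning": {"draws": 300, "warmup": 600, "n_walkers": None,
                  "sigma_bounds": [1.0, 1.5], "q0": 0.5},
    "fir": {"n_taps": 48, "source_rate_hz": 0.5, "analysis_rate_hz": 3.0,
            "alpha": 0.0125, "window_s": [0.0, 8.0], "penalty": None},
    "rf": {"n_trees": 2000, "mtry": None, "train_fraction": 2 / 3,
           "tune": False, "good_learners_only": False,
           "shuffle_labels": False, "add_random_control": False},
}


def _merge(base: dict, override: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def build_configs(config: dict):
    cfg = _merge(DEFAULT_CONFIG, config)
    task_cfg = task.TaskConfig(**cfg["task"])
    hyper_kw = {}
    if cfg["cohort"].get("mu_z"):
        hyper_kw["mu_z"] = dict(cfg["cohort"]["mu_z"])
    if cfg["cohort"].get("sigma_z"):
        hyper_kw["sigma_z"] = dict(cfg["cohort"]["sigma_z"])
    hyper = simulate.GroupHyperParams(**hyper_kw)
    roi_cfg = signals.RoiSignalConfig(**cfg["signal"])
    return cfg, task_cfg, hyper, roi_cfg


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict, seed: int, out_dir, stages=STAGES) -> dict:
    """Execute the requested stages in order; returns the manifest dict.

    A stage failure halts the run; the manifest written so far records
    partial completion. Later stages require the artifacts of earlier
    ones and fail with an explicit message naming the missing stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "pipeline.log")
    log.addHandler(fh)

    cfg, task_cfg, hyper, roi_cfg = build_configs(config)
    manifest = {"config": cfg, "config_hash": _config_hash(cfg),
                "seed": int(seed), "stages": {}, "status": "running"}
    manifest_path = out / "manifest.json"

    def checkpoint():
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    try:
        for stage in stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            t0 = time.time()
            stage_seed = io.derive_seed(seed, stage)
            log.info("stage %s (seed %d)", stage, stage_seed)
            outputs = _run_stage(stage, cfg, task_cfg, hyper, roi_cfg,
                                 stage_seed, out)
            manifest["stages"][stage] = {
                "seed": stage_seed, "outputs": outputs,
                "elapsed_s": round(time.time() - t0, 2)}
            checkpoint()
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed at {stage}: {exc}"
        checkpoint()
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
    checkpoint()
    return manifest


def _require(path: Path, producer: str):
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path.name}: run the '{producer}' stage first")
    return path


def _run_stage(stage, cfg, task_cfg, hyper, roi_cfg, seed, out: Path) -> list:
    if stage == "simulate":
        records, qtraces, cohort = simulate.simulate_cohort(
            hyper, task_cfg, cfg["cohort"]["n_subjects"], seed)
        io.write_trials(records, out / "trials.tsv")
        qtraces.to_csv(out / "qtrace.csv", index=False)
        pd.DataFrame([vars(p) for p in cohort]).assign(
            subject_id=[f"sub-{i + 1:02d}" for i in range(len(cohort))]
        ).to_csv(out / "true_params.csv", index=False)
        betas = signals.synthesize_trial_betas(
            records, qtraces, roi_cfg, io.derive_seed(seed, "betas"))
        betas.to_csv(out / "betas.csv", index=False)
        first = records["subject_id"] == records["subject_id"].iloc[0]
        series, truth = signals.synthesize_roi_timeseries(
            records[first].reset_index(drop=True),
            qtraces[first].reset_index(drop=True),
            roi_cfg, seed=io.derive_seed(seed, "series"))
        series.to_csv(out / "series_sub-01.tsv", sep="\t", index=False)
        truth.to_csv(out / "series_truth_sub-01.csv", index=False)
        return ["trials.tsv", "qtrace.csv", "true_params.csv", "betas.csv",
                "series_sub-01.tsv", "series_truth_sub-01.csv"]

    if stage == "fit-q":
        records = io.read_trials(_require(out / "trials.tsv", "simulate"))
        q = cfg["qlearning"]
        results = hierarchical.fit_hierarchical(
            records, draws=q["draws"], warmup=q["warmup"],
            n_walkers=q["n_walkers"], seed=seed,
            sigma_bounds=tuple(q["sigma_bounds"]), q0=q["q0"])
        results.summary().to_csv(out / "posterior_summary.csv")
        results.subject_params().to_csv(out / "subject_params.csv", index=False)
        np.save(out / "posterior_draws.npy", results.flat_draws())
        return ["posterior_summary.csv", "subject_params.csv",
                "posterior_draws.npy"]

    if stage == "deconvolve":
        records = io.read_trials(_require(out / "trials.tsv", "simulate"))
        qtraces = pd.read_csv(_require(out / "qtrace.csv", "simulate"))
        f = cfg["fir"]
        coefs = []
        sid = records["subject_id"].iloc[0]
        series = pd.read_csv(
            _require(out / f"series_{sid}.tsv", "simulate"), sep="\t")
        mask = ((records["subject_id"] == sid) & (records["phase"] == "learning")
                & (records["choice"] != "MISS"))
        rec = records[mask]
        tr = qtraces[mask.to_numpy()]
        events = {"stimulus": rec["onset_s"].to_numpy(),
                  "feedback": rec["feedback_onset_s"].to_numpy()}
        modulators = {
            "q_chosen": ("stimulus", tr["q_chosen"].to_numpy()),
            "q_unchosen": ("stimulus", tr["q_unchosen"].to_numpy()),
            "rpe_signed": ("feedback", tr["rpe_signed"].to_numpy()),
            "rpe_unsigned": ("feedback", tr["rpe_unsigned"].to_numpy()),
        }
        model = fir.FIRModel(series, events, modulators, n_taps=f["n_taps"],
                             source_rate_hz=f["source_rate_hz"],
                             analysis_rate_hz=f["analysis_rate_hz"])
        res = model.fit(penalty=f["penalty"], seed=seed)
        df = res.coefficients.assign(subject=sid, penalty=res.penalty)
        coefs.append(df)
        tidy = pd.concat(coefs, ignore_index=True)
        tidy.to_csv(out / "fir_coefficients.csv", index=False)
        return ["fir_coefficients.csv"]

    if stage == "decode":
        betas = pd.read_csv(_require(out / "betas.csv", "simulate"))
        r = cfg["rf"]
        if r["good_learners_only"]:
            records = io.read_trials(_require(out / "trials.tsv", "simulate"))
            good = qlearning.filter_good_learners(
                qlearning.behavior_summary(records))
            betas = betas[betas["subject_id"].isin(good)]
        matrix = forest.assemble_matrix(
            [g for _, g in betas.groupby("subject_id", sort=True)], seed)
        report, extras = forest.decode(
            matrix, n_trees=r["n_trees"], mtry=r["mtry"],
            train_fraction=r["train_fraction"], seed=seed, tune=r["tune"],
            shuffle_labels=r["shuffle_labels"],
            add_random_control=r["add_random_control"])
        (out / "rf_report.json").write_text(
            json.dumps(report.to_dict(), indent=2))
        report.importance.to_csv(out / "rf_importance.csv", index=False)
        pd.DataFrame({"vote": report.votes}).to_csv(
            out / "rf_votes.csv", index=False)
        return ["rf_report.json", "rf_importance.csv", "rf_votes.csv"]

    raise ValueError(f"unknown stage {stage!r}")
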