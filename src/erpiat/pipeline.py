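"""End-to-end pipeline orchestration with a reproducibility manifest.

Stages: simulate -> score -> preprocess -> fit -> cluster -> roc -> report.
Each stage reads only files produced by earlier stages (or supplied
externally), records its parameters and outputs in the run manifest, and
derives its randomness from the master seed, so a rerun with the same
config reproduces every stochastic output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, classify, cluster as clustermod, glm, io as eio, preprocess, synth
from .montage import load_montage
from .cluster import build_adjacency, permutation_null, report_clusters

__all__ = ["RunConfig", "DependencyError", "run_pipeline", "make_report"]

logger = logging.getLogger("erpiat")

STAGES = ("simulate", "score", "preprocess", "fit", "cluster", "roc", "report")


class DependencyError(RuntimeError):
    """A stage needs outputs of a stage that did not run."""


@dataclass
class RunConfig:
    """Master configuration: stage toggles + per-stage parameter blocks."""

    out_dir: str = "erpiat_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    log_level: str = "INFO"
    simulation: dict = field(default_factory=dict)   # SimulationConfig kwargs
    scoring: dict = field(default_factory=dict)      # ScoringPolicy kwargs
    preprocessing: dict = field(default_factory=dict)
    fitting: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    roc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}; valid stages are {STAGES}")
        self.stages = tuple(self.stages)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)


def _params_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence(master, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    manifest: dict = {"seed": config.seed, "config": config.to_dict(), "stages": []}

    def record(stage: str, params: dict, files: dict) -> None:
        manifest["stages"].append({
            "stage": stage,
            "params": params,
            "params_hash": _params_hash(params),
            "outputs": {k: str(v) for k, v in files.items()},
        })

    def need(path: Path, producer: str, consumer: str) -> Path:
        if not path.exists():
            raise DependencyError(
                f"stage {consumer!r} requires {path.name} from stage {producer!r}, "
                "which did not run"
            )
        return path

    study = out / "study"

    try:
        if "simulate" in config.stages:
            sim_cfg = synth.SimulationConfig(seed=config.seed, **config.simulation)
            synth.write_fixture_study(sim_cfg, study)
            logger.info("simulate: wrote synthetic study to %s", study)
            record("simulate", sim_cfg.to_dict(), {
                "study_dir": study, "epochs": study / "epochs.h5",
                "trials": study / "trials.csv", "covariates": study / "covariates.csv",
                "montage": study / "montage.txt",
            })

        if "score" in config.stages:
            trials = eio.read_trials(need(study / "trials.csv", "simulate", "score"))
            policy = behavior.ScoringPolicy(**config.scoring)
            dscores, unscorable = behavior.score_all(trials, policy)
            dscores.to_csv(out / "dscores.csv", index=False)
            (out / "unscorable.json").write_text(json.dumps(unscorable))
            for pid in unscorable:
                logger.info("score: participant %s unscorable, excluded", pid)
            record("score", asdict(policy) | {"recode_bounds": list(policy.recode_bounds or [])},
                   {"dscores": out / "dscores.csv", "unscorable": out / "unscorable.json"})

        if "preprocess" in config.stages:
            prep = {
                "baseline": (-200.0, 0.0), "peak_to_peak_max": 100.0,
                "max_bad_channels_per_trial": 10, "channel_bad_fraction": 0.3,
                "min_epochs": 10, "decimate": 4,
            } | config.preprocessing
            epochs = eio.read_epochs(need(study / "epochs.h5", "simulate", "preprocess"))
            montage = load_montage(need(study / "montage.txt", "simulate", "preprocess"))
            by_pid: dict[str, dict] = {}
            for ep in epochs:
                by_pid.setdefault(ep.participant_id, {})[ep.condition] = ep
            contrasts, qc_log = [], []
            for pid, conds in sorted(by_pid.items()):
                cleaned = {}
                for cond, ep in conds.items():
                    ep = preprocess.baseline_correct(ep, tuple(prep["baseline"]))
                    ep = preprocess.reject_artifacts(
                        ep, montage.positions,
                        peak_to_peak_max=prep["peak_to_peak_max"],
                        max_bad_channels_per_trial=prep["max_bad_channels_per_trial"],
                        channel_bad_fraction=prep["channel_bad_fraction"],
                    )
                    for entry in ep.interpolation_log:
                        logger.info("preprocess %s/%s: %s", pid, cond, entry)
                    cleaned[cond] = ep
                decision = preprocess.qc_gate(
                    cleaned["death_congruent"], cleaned["life_congruent"],
                    min_epochs=prep["min_epochs"],
                )
                qc_log.append(asdict(decision))
                if decision.included:
                    contrasts.append(preprocess.build_contrast(
                        cleaned["death_congruent"], cleaned["life_congruent"],
                        decimate=prep["decimate"],
                    ))
                else:
                    logger.info("preprocess: excluded %s (%s)", pid, decision.reason)
            if not contrasts:
                raise RuntimeError("no participant passed QC")
            eio.write_contrasts(out / "contrasts.h5", contrasts)
            (out / "qc_report.json").write_text(json.dumps(qc_log, indent=2))
            record("preprocess", {k: (list(v) if isinstance(v, tuple) else v) for k, v in prep.items()},
                   {"contrasts": out / "contrasts.h5", "qc_report": out / "qc_report.json"})

        if "fit" in config.stages:
            fit_params = {"method": "robust"} | config.fitting
            contrasts = eio.read_contrasts(need(out / "contrasts.h5", "preprocess", "fit"))
            covariates = eio.read_covariates(need(study / "covariates.csv", "simulate", "fit"))
            dscores = pd.read_csv(need(out / "dscores.csv", "score", "fit"))
            included = [c.participant_id for c in contrasts]
            dsub = dscores[dscores["participant_id"].isin(included)]
            design = glm.build_design(covariates, dsub, participants=included)
            field_ = glm.fit_field(contrasts, design, method=fit_params["method"])
            eio.write_glm_field(out / "glm.h5", field_)
            report = {
                "method": field_.method, "df_model": field_.df_model,
                "df_resid": field_.df_resid, "n_participants": len(included),
                "mean_robust_weight": field_.mean_robust_weight,
                "n_fallback_cells": int(field_.robust_fallback.sum())
                if field_.robust_fallback is not None else 0,
            }
            (out / "fit_report.json").write_text(json.dumps(report, indent=2))
            record("fit", fit_params, {"glm": out / "glm.h5", "fit_report": out / "fit_report.json"})

        if "cluster" in config.stages:
            cl_params = {
                "regressors": ["group", "d_score"], "n_permutations": 1000,
                "cluster_forming_p": 0.05, "distance_threshold_mm": 40.0,
                "alpha": 0.05,
            } | config.clustering
            contrasts = eio.read_contrasts(need(out / "contrasts.h5", "preprocess", "cluster"))
            covariates = eio.read_covariates(need(study / "covariates.csv", "simulate", "cluster"))
            dscores = pd.read_csv(need(out / "dscores.csv", "score", "cluster"))
            montage = load_montage(need(study / "montage.txt", "simulate", "cluster"))
            included = [c.participant_id for c in contrasts]
            design = glm.build_design(
                covariates, dscores[dscores["participant_id"].isin(included)],
                participants=included,
            )
            graph = build_adjacency(montage, cl_params["distance_threshold_mm"])
            seed = _stage_seed(config.seed, "cluster")
            files = {}
            summaries = {}
            for reg in cl_params["regressors"]:
                res = permutation_null(
                    contrasts, design, reg, graph,
                    n_permutations=cl_params["n_permutations"], seed=seed,
                    cluster_forming_p=cl_params["cluster_forming_p"],
                )
                table = report_clusters(res)
                table.to_csv(out / f"clusters_{reg}.csv", index=False)
                np.savetxt(out / f"null_mass_{reg}.csv", res.null_distribution, fmt="%.6f")
                files[f"clusters_{reg}"] = out / f"clusters_{reg}.csv"
                files[f"null_mass_{reg}"] = out / f"null_mass_{reg}.csv"
                summaries[reg] = {
                    "n_clusters": len(res.clusters),
                    "n_significant": len(res.significant(cl_params["alpha"])),
                    "threshold_F": res.threshold_F,
                    "seed": seed,
                }
            (out / "cluster_summary.json").write_text(json.dumps(summaries, indent=2))
            files["cluster_summary"] = out / "cluster_summary.json"
            record("cluster", cl_params, files)

        if "roc" in config.stages:
            roc_params = {"predictors": None, "cv": 5, "regressor": "group"} | config.roc
            contrasts = eio.read_contrasts(need(out / "contrasts.h5", "preprocess", "roc"))
            covariates = eio.read_covariates(need(study / "covariates.csv", "simulate", "roc"))
            dscores = pd.read_csv(need(out / "dscores.csv", "score", "roc"))
            cl_table_path = need(out / f"clusters_{roc_params['regressor']}.csv", "cluster", "roc")
            cl_table = pd.read_csv(cl_table_path)
            cluster_feats = {}
            if len(cl_table):
                # top-mass cluster of the requested regressor as ERP feature
                row = cl_table.iloc[0]
                chans = {c: i for i, c in enumerate(contrasts[0].channel_names)}
                t0 = np.argmin(np.abs(contrasts[0].times_ms - row["start_ms"]))
                t1 = np.argmin(np.abs(contrasts[0].times_ms - row["end_ms"]))
                cells = [
                    (chans[ch], t)
                    for ch in str(row["channels"]).split(",")
                    for t in range(int(t0), int(t1) + 1)
                ]
                feat = classify.extract_cluster_feature(
                    contrasts, clustermod.Cluster(cells=cells, mass=float(row["mass"]))
                )
                cluster_feats["erp_cluster_mean"] = feat
            included = [c.participant_id for c in contrasts]
            features = classify.build_feature_table(
                covariates[covariates["participant_id"].isin(included)],
                dscores[dscores["participant_id"].isin(included)],
                cluster_feats,
            )
            predictors = roc_params["predictors"] or (
                ["erp_cluster_mean", "d_score"] if cluster_feats else ["d_score"]
            )
            seed = _stage_seed(config.seed, "roc")
            roc_res = classify.fit_roc(
                features, predictors, cv=roc_params["cv"], seed=seed
            )
            pd.DataFrame({
                "fpr": roc_res.fpr, "tpr": roc_res.tpr, "threshold": roc_res.thresholds,
            }).to_csv(out / "roc_points.csv", index=False)
            (out / "roc_summary.json").write_text(json.dumps({
                "auc": roc_res.auc, "predictors": list(roc_res.predictors),
                "coefficients": roc_res.coefficients, "cv_scheme": roc_res.cv_scheme,
                "penalized_fallback": roc_res.penalized_fallback, "seed": seed,
            }, indent=2))
            record("roc", {"predictors": list(predictors), "cv": roc_params["cv"]},
                   {"roc_points": out / "roc_points.csv", "roc_summary": out / "roc_summary.json"})

        if "report" in config.stages:
            record("report", {}, {"report": out / "report.txt"})
            (out / "report.txt").write_text(make_report(manifest, out))

        with open(out / "manifest.json", "w") as fhandle:
            json.dump(manifest, fhandle, indent=2)
        return manifest
    finally:
        logger.removeHandler(fh)
        fh.close()


def make_report(manifest: dict, out_dir) -> str:
    """Assemble the run's human-readable summary document.

    Sections appear only when their stage outputs exist; missing stages
    are listed as explicit gaps, so a partial run still reports honestly.
    """
    out = Path(out_dir)
    lines = ["ERP / DS-IAT pipeline report", "=" * 32, f"master seed: {manifest['seed']}", ""]
    ran = {s["stage"] for s in manifest["stages"]}

    dscore_path = out / "dscores.csv"
    cov_path = out / "study" / "covariates.csv"
    if dscore_path.exists() and cov_path.exists():
        dscores = pd.read_csv(dscore_path)
        covariates = pd.read_csv(cov_path)
        try:
            res = behavior.d_score_group_test(dscores, covariates)
            lines += [
                "Behavioral D scores (ANCOVA on group, adjusting age + gender)",
                *(
                    f"  {g}: mean D = {res['group_means'][g]:+.3f} "
                    f"(SE {res['group_sems'][g]:.3f}, n = {res['n'][g]})"
                    for g in sorted(res["group_means"])
                ),
                f"  adjusted group difference (sibs - control) = "
                f"{res['adjusted_group_difference']:+.3f}, "
                f"F = {res['F']:.2f}, p = {res['p']:.4f}", "",
            ]
        except ValueError as exc:
            lines += [f"Behavioral D scores: not testable ({exc})", ""]
    else:
        lines += ["Behavioral D scores: MISSING (score stage did not run)", ""]

    qc_path = out / "qc_report.json"
    if qc_path.exists():
        qc = json.loads(qc_path.read_text())
        excluded = [q for q in qc if not q["included"]]
        lines.append(f"QC: {len(qc) - len(excluded)}/{len(qc)} participants included")
        for q in excluded:
            lines.append(f"  excluded {q['participant_id']}: {q['reason']}")
        lines.append("")
    else:
        lines += ["QC: MISSING (preprocess stage did not run)", ""]

    any_cluster = False
    for reg in ("group", "d_score"):
        path = out / f"clusters_{reg}.csv"
        if not path.exists():
            continue
        any_cluster = True
        table = pd.read_csv(path)
        lines.append(f"Clusters for regressor {reg!r}: {len(table)} found")
        for _, row in table.iterrows():
            lines.append(
                f"  {row['start_ms']:.0f}-{row['end_ms']:.0f} ms, "
                f"{row['n_channels']} channels, mass {row['mass']:.1f}, "
                f"cluster p = {row['p_corrected']:.4f}"
            )
        lines.append("")
    if not any_cluster:
        lines += ["Clusters: MISSING (cluster stage did not run)", ""]

    roc_path = out / "roc_summary.json"
    if roc_path.exists():
        roc = json.loads(roc_path.read_text())
        lines += [
            f"ROC ({' + '.join(roc['predictors'])}; {roc['cv_scheme']}): "
            f"AUC = {roc['auc']:.3f}"
            + (" [penalized fallback]" if roc["penalized_fallback"] else ""),
            "",
        ]
    else:
        lines += ["ROC: MISSING (roc stage did not run)", ""]

    lines.append(f"stages run: {', '.join(sorted(ran)) if ran else 'none'}")
    return "\n".join(lines) + "\n"
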