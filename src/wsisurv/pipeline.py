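"""End-to-end orchestration: simulate/encode -> train -> score -> stratify ->
analyze -> explain, with a run manifest for reproducibility.

The train-on-cohort-A / deploy-on-cohort-B workflow is first-class: the
binarization threshold is derived once from the training cohort's scores,
embedded in the checkpoint, and reused verbatim when scoring an external
cohort — deployment never recomputes it. Every artifact is checksummed into
``manifest.json``; re-running a stage whose outputs already exist with
matching checksums is a no-op, while a mismatch aborts rather than silently
reusing stale files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import attribute_bag, top_tiles
from .bags import FeatureBag, merge_patient_bags, read_bag, write_bag
from .io import (read_clinical, read_manifest, sha256_file, write_clinical,
                 write_manifest, write_scores)
from .model import MILRiskModel, ModelConfig, load_checkpoint, save_checkpoint
from .stratify import derive_threshold, stratify_cohort, subgroup_table
from .survstats import (LandmarkSpec, cox_fit, dfs_at, km_fit, labels_from_frame,
                        landmark_filter, logrank)
from .synth import SynthCohortSpec, generate_cohort
from .training import TrainConfig, score_bags, split_patients, train

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "score_external",
           "analyze_strata"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: Path
    cohort: SynthCohortSpec
    deploy_cohort: SynthCohortSpec | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    tile_um: float = 256.0
    top_k: int = 8
    seed: int = 0


@dataclass
class RunManifest:
    version: str = __version__
    config: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, inputs: dict, outputs: dict) -> None:
        self.stages[stage] = {"inputs": inputs, "outputs": outputs,
                              "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"version": self.version, "config": self.config, "stages": self.stages},
            indent=2, default=str))


def _checksums(paths) -> dict:
    return {str(p): sha256_file(p) for p in paths}


def _stage_fresh(manifest: RunManifest, stage: str) -> bool:
    """True when the stage's recorded outputs all exist with matching hashes."""
    rec = manifest.stages.get(stage)
    if rec is None:
        return False
    for p, digest in rec["outputs"].items():
        if not Path(p).exists():
            return False
        if sha256_file(p) != digest:
            raise RuntimeError(
                f"checksum mismatch for {p} (stage {stage!r}); refusing to resume "
                "on stale artifacts — delete the output directory to rerun")
    return True


def _load_manifest(path) -> RunManifest:
    if Path(path).exists():
        data = json.loads(Path(path).read_text())
        return RunManifest(version=data["version"], config=data["config"],
                           stages=data["stages"])
    return RunManifest()


def _write_cohort(cohort, bag_dir: Path, clinical_path: Path, manifest_path: Path,
                  encoder_name: str, tile_um: float):
    bag_dir.mkdir(parents=True, exist_ok=True)
    pairs = []
    for bag in cohort.bags:
        p = bag_dir / f"{bag.slide_id}.h5"
        write_bag(bag, p, encoder_name=encoder_name, tile_um=tile_um, overwrite=True)
        pairs.append((bag.patient_id, str(p)))
    write_manifest(pairs, manifest_path)
    write_clinical(cohort.clinical, clinical_path)


def load_patient_bags(manifest: pd.DataFrame) -> dict:
    """Read all bags and merge multi-slide patients."""
    per_patient: dict[str, list[FeatureBag]] = {}
    for row in manifest.itertuples(index=False):
        per_patient.setdefault(str(row.patient_id), []).append(read_bag(row.bag_path))
    return {pid: merge_patient_bags(bags) for pid, bags in per_patient.items()}


def score_external(checkpoint_path, bags: dict) -> pd.DataFrame:
    """Deploy-only scoring: frozen model and frozen threshold from the checkpoint."""
    model, meta = load_checkpoint(checkpoint_path)
    if "threshold" not in meta:
        raise ValueError("checkpoint carries no binarization threshold")
    pids = sorted(bags)
    scores = score_bags(model, [bags[p] for p in pids])
    return pd.DataFrame({"patient_id": pids, "risk": scores,
                         "threshold": meta["threshold"]})


def analyze_strata(strat: pd.DataFrame, clinical: pd.DataFrame,
                   landmarks=(3.0, 6.0), dfs_timepoints=(24.0,)) -> dict:
    """KM / log-rank / Cox analyses over DL classes and joint strata."""
    df = strat.merge(clinical, on="patient_id")
    labels = labels_from_frame(df)
    out: dict = {"n": len(df)}

    def group_block(key):
        groups = {}
        for val, sub in df.groupby(key):
            if key == "stratum" and val == "NA":
                continue
            groups[str(val)] = labels_from_frame(sub)
        block = {"groups": {}}
        for name, ls in groups.items():
            curve = km_fit(ls)
            entry = {"n": curve.n, "events": curve.n_events}
            for t in dfs_timepoints:
                s, extr = dfs_at(curve, t)
                entry[f"dfs_{int(t)}m"] = s
                if extr:
                    entry[f"dfs_{int(t)}m_extrapolated"] = True
            block["groups"][name] = entry
        if len(groups) >= 2 and all(len(v) for v in groups.values()):
            chi2, p = logrank(groups)
            block["logrank_chi2"], block["logrank_p"] = chi2, p
        return block

    out["dl_class"] = group_block("dl_class")
    out["stratum"] = group_block("stratum")

    # univariate Cox on the DL class (high vs low)
    x = (df["dl_class"] == "high").astype(float).to_numpy()
    if 0 < x.sum() < len(x):
        fit = cox_fit(labels, x, names=["dl_high"])
        out["cox_dl_high"] = fit.summary().iloc[0].to_dict()

    out["landmark"] = {}
    for lm in landmarks:
        try:
            lm_labels = landmark_filter(labels, LandmarkSpec(lm))
        except ValueError:
            continue
        kept = {l.patient_id for l in lm_labels}
        sub = df[df["patient_id"].isin(kept)]
        xs = (sub["dl_class"] == "high").astype(float).to_numpy()
        if 0 < xs.sum() < len(xs):
            order = {l.patient_id: l for l in lm_labels}
            fit = cox_fit([order[p] for p in sub["patient_id"]], xs, names=["dl_high"])
            out["landmark"][f"{int(lm)}m"] = fit.summary().iloc[0].to_dict()
    return out


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run every stage on synthetic cohorts; see module docstring for resume rules."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mpath = out / "manifest.json"
    manifest = _load_manifest(mpath)
    manifest.config = {
        "cohort": dataclasses.asdict(cfg.cohort),
        "deploy_cohort": dataclasses.asdict(cfg.deploy_cohort) if cfg.deploy_cohort else None,
        "model": dataclasses.asdict(cfg.model),
        "train": dataclasses.asdict(cfg.train),
        "seed": cfg.seed,
    }

    # -- simulate -------------------------------------------------------------
    train_manifest = out / "bags_train.csv"
    train_clinical = out / "clinical_train.csv"
    deploy_manifest = out / "bags_deploy.csv"
    deploy_clinical = out / "clinical_deploy.csv"
    if not _stage_fresh(manifest, "simulate"):
        cohort = generate_cohort(cfg.cohort)
        _write_cohort(cohort, out / "bags_train", train_clinical, train_manifest,
                      "synthetic", cfg.tile_um)
        outputs = [train_manifest, train_clinical]
        if cfg.deploy_cohort is not None:
            deploy = generate_cohort(cfg.deploy_cohort)
            _write_cohort(deploy, out / "bags_deploy", deploy_clinical,
                          deploy_manifest, "synthetic", cfg.tile_um)
            outputs += [deploy_manifest, deploy_clinical]
        manifest.record("simulate", {}, _checksums(outputs))
        manifest.save(mpath)
        log.info(json.dumps({"stage": "simulate", "status": "done"}))

    bags = load_patient_bags(read_manifest(train_manifest))
    clinical = read_clinical(train_clinical)

    # -- train ----------------------------------------------------------------
    ckpt = out / "checkpoint.npz"
    if not _stage_fresh(manifest, "train"):
        labels = labels_from_frame(clinical)
        splits = split_patients([l.patient_id for l in labels],
                                cfg.train.split_ratio, cfg.train.seed)
        model, tlog = train(bags, labels, cfg.model, cfg.train, splits=splits)
        train_scores = score_bags(model, [bags[p] for p in splits[0]])
        threshold = derive_threshold(train_scores)
        save_checkpoint(ckpt, model, meta={
            "threshold": threshold, "encoder_name": "synthetic",
            "tile_um": cfg.tile_um, "best_epoch": tlog.best_epoch,
            "best_val_cindex": tlog.best_val_cindex,
        })
        (out / "training_log.json").write_text(json.dumps({
            "epoch_losses": tlog.epoch_losses,
            "epoch_val_cindex": tlog.epoch_val_cindex,
            "best_epoch": tlog.best_epoch,
            "best_val_cindex": tlog.best_val_cindex,
        }, indent=2))
        manifest.record("train", _checksums([train_manifest, train_clinical]),
                        _checksums([ckpt, out / "training_log.json"]))
        manifest.save(mpath)
        log.info(json.dumps({"stage": "train", "status": "done",
                             "best_val_cindex": tlog.best_val_cindex}))

    # -- score + stratify + analyze on the deployment cohort -------------------
    target_manifest = deploy_manifest if cfg.deploy_cohort is not None else train_manifest
    target_clinical = deploy_clinical if cfg.deploy_cohort is not None else train_clinical
    scores_path = out / "scores.csv"
    strat_path = out / "stratification.csv"
    subgroup_path = out / "subgroups.csv"
    analysis_path = out / "analysis.json"
    if not _stage_fresh(manifest, "analyze"):
        target_bags = load_patient_bags(read_manifest(target_manifest))
        target_clin = read_clinical(target_clinical)
        scored = score_external(ckpt, target_bags)
        write_scores(scored, scores_path)
        strat = stratify_cohort(scored[["patient_id", "risk"]], target_clin,
                                threshold=float(scored["threshold"].iloc[0]))
        strat.to_csv(strat_path, index=False)
        subgroup_table(strat).to_csv(subgroup_path, index=False)
        analysis = analyze_strata(strat, target_clin)
        analysis_path.write_text(json.dumps(analysis, indent=2, default=float))
        manifest.record("analyze", _checksums([ckpt, target_manifest, target_clinical]),
                        _checksums([scores_path, strat_path, subgroup_path, analysis_path]))
        manifest.save(mpath)
        log.info(json.dumps({"stage": "analyze", "status": "done"}))

    # -- explain --------------------------------------------------------------
    attr_path = out / "attribution.csv"
    if not _stage_fresh(manifest, "explain"):
        model, _meta = load_checkpoint(ckpt)
        target_bags = load_patient_bags(read_manifest(target_manifest))
        rows = []
        for pid in sorted(target_bags)[:4]:   # a few exemplar patients
            bag = target_bags[pid]
            amap = attribute_bag(bag, model)
            tops = {tuple(c) for c in top_tiles(amap, min(cfg.top_k, bag.n_tiles))}
            for (x, y), g, pn, wsc in zip(amap.coords, amap.gradcam,
                                          amap.tile_pred_norm, amap.weighted):
                rows.append({"slide_id": amap.slide_id, "x": int(x), "y": int(y),
                             "gradcam": g, "pred_norm": pn, "weighted": wsc,
                             "top_tile": (x, y) in tops})
        pd.DataFrame(rows).to_csv(attr_path, index=False)
        manifest.record("explain", _checksums([ckpt]), _checksums([attr_path]))
        manifest.save(mpath)
        log.info(json.dumps({"stage": "explain", "status": "done"}))

    return manifest
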