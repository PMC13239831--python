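"""End-to-end pipeline composition and input validation.

Stages: simulate → build-fcn → train → evaluate → explain.  Each stage reads
its predecessor's on-disk artifacts; a run manifest records the config hash,
seed, package version and per-stage wall time so a run can be reproduced
exactly from its artifact directory.
"""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_hash, dump_resolved
from .fcn import PATTERNS, ConnectivityMatrix, PatternGraph, SrConfig
from .interpret import gradcam_node_importance, importance_report
from .synthetic import default_config, read_cohort, simulate_cohort, write_cohort
from .training import (TrainConfig, ablation_study, cohort_graphs, evaluate,
                       export_embeddings, train_model)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "build-fcn", "train", "evaluate", "explain")

__all__ = ["STAGES", "run_pipeline", "validate_inputs"]


def _train_config(cfg: PipelineConfig, seed: int) -> TrainConfig:
    t = cfg.training
    return TrainConfig(learning_rate=t.learning_rate,
                       weight_decay=t.weight_decay, epochs=t.epochs,
                       dropout=cfg.model.dropout, seed=seed,
                       train_fraction=t.train_fraction,
                       val_fraction=t.val_fraction,
                       test_fraction=t.test_fraction, k_folds=t.k_folds)


def _save_graphs(graphs, labels, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    arrays = {}
    for i, g in enumerate(graphs):
        for pat, pg in g.items():
            arrays[f"adj/{i}/{pat}"] = pg.adjacency.weights
    np.savez(os.path.join(directory, "graphs.npz"),
             labels=np.asarray(labels, dtype=int),
             roi_labels=np.array(graphs[0][next(iter(graphs[0]))].adjacency.roi_labels),
             patterns=np.array(sorted({p for g in graphs for p in g})),
             **arrays)


def _load_graphs(directory: str):
    path = os.path.join(directory, "graphs.npz")
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"no graphs.npz under {directory}; run the build-fcn stage first")
    data = np.load(path, allow_pickle=False)
    labels = data["labels"]
    roi_labels = [str(x) for x in data["roi_labels"]]
    patterns = [str(p) for p in data["patterns"]]
    graphs = []
    for i in range(len(labels)):
        entry = {}
        for pat in patterns:
            w = data[f"adj/{i}/{pat}"]
            cm = ConnectivityMatrix(weights=w, pattern=pat,
                                    roi_labels=roi_labels, canonical=True)
            entry[pat] = PatternGraph(node_features=w.copy(), adjacency=cm,
                                      pattern=pat)
        graphs.append(entry)
    return graphs, labels


def run_pipeline(cfg: PipelineConfig, out_dir: str, seed: int,
                 stages: tuple[str, ...] = STAGES) -> str:
    """Run the requested prefix of the pipeline, writing artifacts to disk.

    Rerunning with an identical config and seed reproduces every metric
    bitwise (all arithmetic is numpy on one thread of control).
    """
    stages = tuple(stages)
    order = [s for s in STAGES if s in stages]
    if order != list(stages):
        raise ValueError(f"stages must follow the order {STAGES}")
    for earlier, later in zip(STAGES, STAGES[1:]):
        if later in stages and earlier not in stages and not _stage_done(out_dir, earlier):
            raise ValueError(f"stage {later!r} requires {earlier!r} to have run first")

    os.makedirs(out_dir, exist_ok=True)
    dump_resolved(cfg, os.path.join(out_dir, "resolved_config.yaml"))
    manifest = {"config_hash": config_hash(cfg), "seed": seed,
                "version": __version__, "stages": {}}
    mpath = os.path.join(out_dir, "run_manifest.json")
    if os.path.exists(mpath):
        with open(mpath) as fh:
            manifest["stages"] = json.load(fh).get("stages", {})

    patterns = tuple(p for p in PATTERNS if p in cfg.training.patterns)
    cohort_dir = os.path.join(out_dir, "cohort")
    fcn_dir = os.path.join(out_dir, "fcn")

    for stage in stages:
        t0 = time.perf_counter()
        if stage == "simulate":
            sim = cfg.simulator
            sc = default_config(n_subjects_per_group=sim.n_subjects_per_group,
                                n_rois=sim.n_rois,
                                n_timepoints=sim.n_timepoints,
                                n_affected=sim.n_affected,
                                self_coupling=sim.self_coupling,
                                cov_coupling=sim.cov_coupling,
                                lag_coupling=sim.lag_coupling,
                                noise_sd=sim.noise_sd, seed=seed)
            write_cohort(simulate_cohort(sc), cohort_dir)
        elif stage == "build-fcn":
            cohort = read_cohort(cohort_dir)
            graphs = cohort_graphs(
                cohort, patterns,
                sr_config=SrConfig(lam=cfg.fcn.sr_lambda,
                                   max_iterations=cfg.fcn.sr_max_iterations,
                                   tolerance=cfg.fcn.sr_tolerance),
                lag_order=cfg.fcn.lag_order,
                thresholds=cfg.fcn.thresholds())
            _save_graphs(graphs, cohort.labels, fcn_dir)
        elif stage == "train":
            graphs, labels = _load_graphs(fcn_dir)
            model, summary = train_model(graphs, labels, patterns,
                                         _train_config(cfg, seed))
            _save_model(model, os.path.join(out_dir, "model.npz"))
            split = summary.split  # type: ignore[attr-defined]
            np.savez(os.path.join(out_dir, "split.npz"),
                     train=split[0], val=split[1], test=split[2])
            summary.histories[0].to_csv(
                os.path.join(out_dir, "training_history.tsv"), sep="\t",
                index=False)
        elif stage == "evaluate":
            graphs, labels = _load_graphs(fcn_dir)
            model = _load_model(os.path.join(out_dir, "model.npz"))
            split = np.load(os.path.join(out_dir, "split.npz"))
            te = split["test"]
            metrics = evaluate(model, [graphs[i] for i in te], labels[te])
            with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
                json.dump(metrics.as_dict(), fh, indent=2)
            abl = ablation_study(graphs, labels, _train_config(cfg, seed))
            abl.to_csv(os.path.join(out_dir, "ablation.tsv"), sep="\t",
                       index=False)
            cohort = read_cohort(cohort_dir)
            emb = export_embeddings(model, graphs,
                                    [s.subject_id for s in cohort.subjects],
                                    labels)
            emb.to_csv(os.path.join(out_dir, "embeddings.tsv"), sep="\t",
                       index=False, float_format="%.17g")
        elif stage == "explain":
            graphs, labels = _load_graphs(fcn_dir)
            model = _load_model(os.path.join(out_dir, "model.npz"))
            split = np.load(os.path.join(out_dir, "split.npz"))
            per_pattern = {p: [] for p in model.patterns}
            for i in split["test"]:
                maps = gradcam_node_importance(
                    model, graphs[i],
                    target_class=cfg.interpretation.target_class,
                    subject_id=str(i))
                for p, imp in maps.items():
                    per_pattern[p].append(imp)
            report = importance_report(per_pattern, k=cfg.interpretation.top_k)
            rows = []
            for pat, table in report["top_k"].items():
                t = table.copy()
                t.insert(0, "pattern", pat)
                rows.append(t)
            pd.concat(rows).to_csv(os.path.join(out_dir, "importance.tsv"),
                                   sep="\t", index=False)
            report["pairwise_overlap"].drop(columns="shared_rois").to_csv(
                os.path.join(out_dir, "importance_overlap.tsv"), sep="\t",
                index=False)
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3)}
        logger.info("stage %s done in %.2fs", stage,
                    manifest["stages"][stage]["seconds"])

    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir


def _stage_done(out_dir: str, stage: str) -> bool:
    markers = {"simulate": "cohort/manifest.tsv", "build-fcn": "fcn/graphs.npz",
               "train": "model.npz", "evaluate": "metrics.json",
               "explain": "importance.tsv"}
    return os.path.exists(os.path.join(out_dir, markers[stage]))


def _save_model(model, path: str) -> None:
    arrays = {"patterns": np.array(model.patterns),
              "dropout_rate": np.array(model.dropout_rate)}
    for p in model.patterns:
        for l, W in enumerate(model.conv_weights[p]):
            arrays[f"conv/{p}/W{l}"] = W
    for l, (W, b) in enumerate(model.head):
        arrays[f"head/{l}/W"] = W
        arrays[f"head/{l}/b"] = b
    np.savez(path, **arrays)


def _load_model(path: str):
    from .gcn import MfcpModel
    data = np.load(path, allow_pickle=False)
    patterns = tuple(str(p) for p in data["patterns"])
    conv = {p: [data[f"conv/{p}/W0"], data[f"conv/{p}/W1"]] for p in patterns}
    head = [(data[f"head/{l}/W"], data[f"head/{l}/b"]) for l in range(3)]
    return MfcpModel(patterns=patterns, conv_weights=conv, head=head,
                     dropout_rate=float(data["dropout_rate"]))


def validate_inputs(path: str) -> dict:
    """Validate a cohort directory: manifest schema, shapes, finiteness, labels.

    Returns a machine-readable report with ``errors`` and ``warnings`` lists;
    unreadable files are reported, never raised.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    manifest_path = os.path.join(path, "manifest.tsv")
    if not os.path.exists(manifest_path):
        return {"errors": [f"missing manifest.tsv in {path}"],
                "warnings": [], "n_subjects": 0}
    try:
        manifest = pd.read_csv(manifest_path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - report, don't throw
        return {"errors": [f"unreadable manifest: {exc}"], "warnings": [],
                "n_subjects": 0}
    missing_cols = {"subject_id", "label", "file"} - set(manifest.columns)
    if missing_cols:
        errors.append(f"manifest missing columns {sorted(missing_cols)}")
        return {"errors": errors, "warnings": warnings_, "n_subjects": 0}
    bad_labels = set(manifest["label"].unique()) - {0, 1}
    if bad_labels:
        errors.append(f"labels outside {{0,1}}: {sorted(bad_labels)}")
    shapes = {}
    for _, row in manifest.iterrows():
        fpath = os.path.join(path, str(row["file"]))
        if not os.path.exists(fpath):
            errors.append(f"{row['subject_id']}: missing file {row['file']}")
            continue
        try:
            values = np.loadtxt(fpath, delimiter="\t", comments="#", ndmin=2)
        except Exception as exc:  # noqa: BLE001
            errors.append(f"{row['subject_id']}: unreadable ({exc})")
            continue
        n_bad = int(np.sum(~np.isfinite(values)))
        if n_bad:
            errors.append(f"{row['subject_id']}: {n_bad} non-finite cells")
        shapes.setdefault(values.shape, []).append(str(row["subject_id"]))
    if len(shapes) > 1:
        detail = "; ".join(f"{s}: {ids}" for s, ids in shapes.items())
        errors.append(f"inconsistent matrix shapes — {detail}")
    if len(manifest) and manifest["label"].nunique() < 2:
        warnings_.append("only one label value present")
    return {"errors": errors, "warnings": warnings_,
            "n_subjects": int(len(manifest))}
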