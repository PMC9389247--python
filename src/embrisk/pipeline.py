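"""End-to-end orchestration: simulate/load -> QC -> normalize -> pathway
scores -> functional clustering -> labels -> SVM-RFE -> final model ->
risk scores -> ROC threshold -> population verdict.

A single global seed fans out to per-stage seeds by a stable derivation,
so changing output paths never changes numerical results.  The resolved
configuration is written next to the outputs of every run.
"""

from __future__ import annotations

import copy
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, preprocess, risk, scoring, svm, synthetic
from .io import CountMatrix, GeneSetCollection, read_gmt, read_mtx_dir, write_gmt, write_mtx_dir

__all__ = [
    "DEFAULT_CONFIG",
    "ConfigError",
    "load_config",
    "resolve_config",
    "stage_seed",
    "simulate_inputs",
    "run_all",
    "PipelineResult",
]

log = logging.getLogger("embrisk")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": None,
    "gmt": None,
    "inputs": [{"preset": "mf_default"}, {"preset": "il_default"}],
    "qc": {"k_mad": 3.0},
    "norm": {"scale": 10000.0},
    "hvg": {"n": 2000, "bins": 20},
    "score": {"method": "module_score", "n_bins": 24, "n_ctrl": 100,
              "alpha": 0.25, "top_frac": 0.1},
    "cluster": {"k": 20, "resolution": 0.5, "prune": 1.0 / 15.0, "n_pcs": 30},
    "labels": {"source": "proembolic_clusters"},
    "train": {
        "train_frac": 0.7,
        "cv_k": 10,
        "n_candidates": 60,
        "rfe_step": 0.1,
        "tol": 1e-3,
        "rfe_c_grid": list(svm.RFE_C_GRID),
        "final_c_grid": list(svm.FINAL_C_GRID),
    },
    "risk": {"dose_cells": 1e6, "calibration_frac": risk.CALIBRATION_FRAC,
             "include_offset": False},
}

_INPUT_KEYS = {"preset", "mtx_dir", "truth", "scenario"}


class ConfigError(ValueError):
    """The pipeline configuration contains unknown or invalid keys."""


def _check_keys(given: dict, allowed: dict | set, path: str) -> None:
    allowed_keys = set(allowed)
    unknown = set(given) - allowed_keys
    if unknown:
        raise ConfigError(f"unknown config key(s) under {path!r}: {sorted(unknown)}")


def resolve_config(overrides: dict | None = None) -> dict:
    """Merge overrides into the defaults, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if not overrides:
        return cfg
    _check_keys(overrides, DEFAULT_CONFIG, "<root>")
    for key, value in overrides.items():
        if isinstance(DEFAULT_CONFIG.get(key), dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {key!r} must be a mapping")
            _check_keys(value, DEFAULT_CONFIG[key], key)
            cfg[key].update(value)
        elif key == "inputs":
            if not isinstance(value, list) or not value:
                raise ConfigError("'inputs' must be a non-empty list")
            for item in value:
                _check_keys(item, _INPUT_KEYS, "inputs[]")
            cfg[key] = value
        else:
            cfg[key] = value
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    return resolve_config(overrides)


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (< 2^31)."""
    entropy = [int(seed), zlib.crc32(stage.encode())]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


@dataclass
class PipelineInput:
    name: str
    counts: CountMatrix
    truth: synthetic.GroundTruth | None = None
    scenario: synthetic.SyntheticScenario | None = None


def _load_input(item: dict, seed: int, index: int) -> PipelineInput:
    if "scenario" in item:
        scenario: synthetic.SyntheticScenario = item["scenario"]
        counts, truth = synthetic.simulate_counts(scenario)
        return PipelineInput(f"scenario{index}", counts, truth, scenario)
    if "preset" in item:
        scenario = synthetic.preset_scenario(item["preset"])
        scenario = scenario.replace(
            seed=stage_seed(seed, f"simulate:{item['preset']}:{index}")
        )
        counts, truth = synthetic.simulate_counts(scenario)
        return PipelineInput(item["preset"], counts, truth, scenario)
    if "mtx_dir" in item:
        counts = read_mtx_dir(item["mtx_dir"])
        truth = None
        if item.get("truth"):
            truth, barcodes = synthetic.read_truth(item["truth"])
            if not np.array_equal(barcodes, counts.barcodes):
                raise ConfigError("truth barcodes do not match the count matrix")
        return PipelineInput(str(item["mtx_dir"]), counts, truth)
    raise ConfigError(f"input needs 'preset', 'scenario' or 'mtx_dir': {item}")


def simulate_inputs(config: dict, out_dir) -> list[Path]:
    """Simulate every configured input and write MTX + truth + GMT."""
    out_dir = Path(out_dir)
    written = []
    for i, item in enumerate(config["inputs"]):
        inp = _load_input(item, config["seed"], i)
        if inp.scenario is None:
            continue
        d = out_dir / inp.name
        write_mtx_dir(inp.counts, d)
        synthetic.write_truth(inp.truth, inp.counts.barcodes, d / "truth.tsv")
        write_gmt(synthetic.make_gene_sets(inp.scenario), d / "sets.gmt")
        written.append(d)
    return written


@dataclass
class PipelineResult:
    """Everything a full run produces, keyed for inspection."""

    expr: preprocess.ExpressionMatrix
    batch_of_cell: np.ndarray
    scores: scoring.PathwayScoreMatrix
    clusters: clustering.ClusterLabels
    proembolic_clusters: set
    y: np.ndarray
    panel: svm.FeatureSelectionResult
    model: svm.LinearSVMModel
    metrics: pd.DataFrame
    roc: risk.ROCResult
    rs: risk.RiskScoreVector
    cell_calls: np.ndarray
    reports: dict = field(default_factory=dict)
    qc_report: pd.DataFrame | None = None


def _candidate_genes(values: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Top-n features by absolute standardized class-mean difference."""
    pos = y == 1
    mu1 = values[pos].mean(axis=0)
    mu0 = values[~pos].mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    score = np.abs(mu1 - mu0) / sd
    order = np.lexsort((np.arange(values.shape[1]), -score))
    return np.sort(order[: min(n, values.shape[1])])


def run_all(config: dict | None = None, **overrides) -> PipelineResult:
    """Execute the full pipeline on the configured inputs."""
    cfg = config if config is not None else resolve_config(overrides or None)
    seed = int(cfg["seed"])

    # --- load or simulate ---------------------------------------------------
    inputs = [_load_input(item, seed, i) for i, item in enumerate(cfg["inputs"])]
    gene_names = inputs[0].counts.gene_names
    for inp in inputs[1:]:
        if not np.array_equal(inp.counts.gene_names, gene_names):
            raise ConfigError("all inputs must share one gene universe")
    if cfg["gmt"]:
        sets = read_gmt(cfg["gmt"])
    elif inputs[0].scenario is not None:
        sets = synthetic.make_gene_sets(inputs[0].scenario)
    else:
        raise ConfigError("a GMT file is required for non-simulated inputs")

    # --- QC per input, then pool -------------------------------------------
    kept_counts, kept_truth, batch, qc_frames = [], [], [], []
    for b, inp in enumerate(inputs):
        metrics = preprocess.compute_qc(inp.counts)
        keep = preprocess.mad_filter(metrics, k=cfg["qc"]["k_mad"])
        frame = metrics.to_frame()
        frame["kept"] = keep.astype(int)
        frame.insert(0, "input", inp.name)
        qc_frames.append(frame)
        log.info("input %s: %d/%d cells pass QC", inp.name, keep.sum(), len(keep))
        kept_counts.append(inp.counts.subset_cells(keep))
        batch.append(np.full(int(keep.sum()), b))
        if inp.truth is not None:
            kept_truth.append(
                synthetic.GroundTruth(
                    inp.truth.program_of_cell[keep],
                    inp.truth.embolic_label[keep],
                    inp.truth.outlier_flag[keep],
                )
            )
    import scipy.sparse as sp

    pooled = CountMatrix(
        values=sp.vstack([c.values for c in kept_counts]).tocsr(),
        barcodes=np.concatenate(
            [np.char.add(f"B{b}-", c.barcodes.astype(str))
             for b, c in enumerate(kept_counts)]
        ),
        gene_ids=inputs[0].counts.gene_ids,
        gene_names=gene_names,
        mito_mask=inputs[0].counts.mito_mask,
    )
    batch_of_cell = np.concatenate(batch)

    # --- normalize, score, cluster -------------------------------------
    expr = preprocess.normalize_log(pooled, scale=cfg["norm"]["scale"])
    n_hvg = min(int(cfg["hvg"]["n"]), expr.n_genes)
    hvg_mask = preprocess.select_hvg(expr, n=n_hvg, n_bins=cfg["hvg"]["bins"])
    method = cfg["score"]["method"]
    score_seed = stage_seed(seed, "score")
    if method == "module_score":
        scores = scoring.score_module(
            expr, sets, n_bins=cfg["score"]["n_bins"],
            n_ctrl=cfg["score"]["n_ctrl"], seed=score_seed,
        )
    elif method == "ssgsea":
        scores = scoring.score_ssgsea(expr, sets, alpha=cfg["score"]["alpha"],
                                      seed=score_seed)
    elif method == "auc_recovery":
        scores = scoring.score_auc_recovery(
            expr, sets, top_frac=cfg["score"]["top_frac"], seed=score_seed)
    else:
        raise ConfigError(f"unknown scoring method {method!r}")

    n_pcs = min(cfg["cluster"]["n_pcs"], scores.scores.shape[1] - 1)
    n_pcs = max(n_pcs, 1)
    emb, _ = preprocess.run_pca(scores.scores, n_pcs=n_pcs)
    snn = clustering.SNNLouvain(
        k=cfg["cluster"]["k"], resolution=cfg["cluster"]["resolution"],
        prune=cfg["cluster"]["prune"],
        random_state=stage_seed(seed, "cluster"),
    )
    snn.fit_predict(emb)
    clusters = snn.clusters_
    log.info("functional clustering: %d clusters", clusters.n_clusters)

    emb_scores = scoring.embolic_scores(
        expr, sets, seed=stage_seed(seed, "embolic_scores"),
        n_bins=cfg["score"]["n_bins"], n_ctrl=cfg["score"]["n_ctrl"],
    )
    pro_clusters = clustering.identify_proembolic_clusters(emb_scores, clusters)
    log.info("pro-embolic clusters: %s", sorted(pro_clusters))

    # --- supervised labels ---------------------------------------------
    source = cfg["labels"]["source"]
    if source == "truth":
        if len(kept_truth) != len(inputs):
            raise ConfigError("labels.source=truth requires truth for every input")
        y = np.concatenate([t.embolic_label for t in kept_truth])
    elif source == "batch":
        if len(inputs) != 2:
            raise ConfigError("labels.source=batch requires exactly two inputs")
        y = np.where(batch_of_cell == 0, 1, -1)
    elif source == "proembolic_clusters":
        y = np.where(np.isin(clusters.label, list(pro_clusters)), 1, -1)
        if len(pro_clusters) == 0:
            raise ConfigError(
                "no pro-embolic cluster identified; cannot derive labels"
            )
    else:
        raise ConfigError(f"unknown label source {source!r}")

    # --- panel selection and final model -------------------------------
    # candidate genes for RFE come from the variable-gene pool
    hvg_idx = np.flatnonzero(hvg_mask)
    cand = hvg_idx[_candidate_genes(expr.values[:, hvg_idx], y,
                                    cfg["train"]["n_candidates"])]
    data = svm.LabeledDataset(expr.values[:, cand], y, expr.gene_names[cand])
    train, test = svm.split_train_test(
        data, train_frac=cfg["train"]["train_frac"],
        seed=stage_seed(seed, "split"),
    )
    panel_result = svm.svm_rfe(
        train, C_grid=cfg["train"]["rfe_c_grid"], cv_k=cfg["train"]["cv_k"],
        seed=stage_seed(seed, "rfe"), step=cfg["train"]["rfe_step"],
        tol=cfg["train"]["tol"],
    )
    log.info("selected panel (%d genes): %s", len(panel_result.selected_panel),
             panel_result.selected_panel)
    model, metrics = svm.select_final_model(
        train, [test], panel_result.selected_panel,
        C_grid=cfg["train"]["final_c_grid"], tol=cfg["train"]["tol"],
        seed=stage_seed(seed, "final_model"),
    )

    # --- risk scores, ROC, verdicts -------------------------------------
    include_b = cfg["risk"]["include_offset"]
    rs_test = risk.compute_rs(model, test.x, gene_names=test.gene_names,
                              include_offset=include_b)
    roc = risk.roc_threshold(rs_test, test.y)
    rs_all = risk.compute_rs(model, data.x, gene_names=data.gene_names,
                             include_offset=include_b)
    calls = risk.classify_cells(rs_all, roc.chosen_threshold, roc.direction)
    reports = {}
    for b, inp in enumerate(inputs):
        mask = batch_of_cell == b
        reports[inp.name] = risk.population_risk(
            calls[mask], dose_cells=cfg["risk"]["dose_cells"],
            calibration_frac=cfg["risk"]["calibration_frac"],
        )
        log.info("%s: %s", inp.name, reports[inp.name].summary())

    result = PipelineResult(
        expr=expr, batch_of_cell=batch_of_cell, scores=scores,
        clusters=clusters, proembolic_clusters=pro_clusters, y=y,
        panel=panel_result, model=model, metrics=metrics, roc=roc,
        rs=rs_all, cell_calls=calls, reports=reports,
        qc_report=pd.concat(qc_frames, ignore_index=True),
    )
    if cfg["out_dir"]:
        _write_artifacts(result, cfg)
    return result


def _write_artifacts(result: PipelineResult, cfg: dict) -> None:
    import dataclasses

    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    dumpable = copy.deepcopy({k: v for k, v in cfg.items() if k != "inputs"})
    dumpable["inputs"] = [
        {"scenario": dataclasses.asdict(item["scenario"])}
        if "scenario" in item else dict(item)
        for item in cfg["inputs"]
    ]
    with open(out / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(dumpable, fh, sort_keys=False)
    result.qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    sc = result.scores.to_frame()
    with open(out / "pathway_scores.tsv", "w") as fh:
        fh.write(f"# method={result.scores.method} params={result.scores.params}\n")
        sc.to_csv(fh, sep="\t")
    pd.DataFrame(
        {"barcode": result.expr.barcodes, "cluster": result.clusters.label}
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    with open(out / "model.txt", "w") as fh:
        fh.write(result.model.to_text())
    result.metrics.to_csv(out / "model_metrics.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "barcode": result.expr.barcodes,
            "margin": result.rs.margin,
            "rs": result.rs.rs,
            "call": result.cell_calls,
        }
    ).to_csv(out / "risk_scores.tsv", sep="\t", index=False)
    with open(out / "risk_report.txt", "w") as fh:
        for name, report in result.reports.items():
            fh.write(f"{name}\t{report.summary()}\n")
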