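"""Pipeline orchestration: simulate -> connectivity -> metrics ->
summaries -> stats, under a single config with a reproducibility manifest.

One global seed is expanded into per-stage child seeds by a fixed counter
scheme (stage index into ``numpy.random.SeedSequence.spawn``), so any
stage can be re-run in isolation and reproduce its outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import DEFAULT_COSTS, compute_connectivity, cost_sweep
from .graphmetrics import metric_sweep
from .stats import group_partial_correlations, interaction_scan, rm_ancova
from .summaries import derive_phenotypes, load_roi_metadata, summarize_subnetworks
from .synthetic import SyntheticConfig, generate_cohort
from . import io

logger = logging.getLogger(__name__)

STAGES = ("simulate", "connectivity", "metrics", "summaries", "stats")


@dataclass
class RunConfig:
    out_dir: str = "amynet_run"
    seed: int = 0
    costs: list[float] = field(default_factory=lambda: list(DEFAULT_COSTS))
    null_iters: int = 10_000
    metric: str = "small_worldness"
    target: str = "whole_network"
    predictor: str = "memory"
    covariates: list[str] = field(default_factory=lambda: ["age", "sex", "education"])
    multiplicity: str = "bonferroni_threshold"
    synthetic: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    idx = STAGES.index(stage)
    child = np.random.SeedSequence(seed).spawn(len(STAGES))[idx]
    return int(child.generate_state(1)[0] % 2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def metric_wide(metrics: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Network-level values of one metric as a subjects x costs table."""
    net = metrics[(metrics["metric"] == metric) & (metrics["roi_id"] == "")]
    return net.pivot(index="subject_id", columns="cost", values="value").sort_index()


def target_wide(summaries: pd.DataFrame, target: str) -> pd.DataFrame:
    sub = summaries[summaries["target"] == target]
    return sub.pivot(index="subject_id", columns="cost", values="value").sort_index()


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest dict.

    A failing stage leaves the completed stages' outputs on disk and a
    manifest marking which stage failed and why.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": dataclasses.asdict(cfg),
        "seeds": {s: stage_seed(cfg.seed, s) for s in STAGES},
        "stages": {},
    }
    state: dict = {}
    try:
        for stage in STAGES:
            t0 = time.time()
            outputs = _run_stage(stage, cfg, out, state)
            manifest["stages"][stage] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 2),
                "outputs": {str(p.name): _digest(p) for p in outputs},
            }
            logger.info("stage %s done (%.1fs)", stage, time.time() - t0)
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": f"{stage}: {exc}"}
        io.write_json(manifest, out / "manifest.json")
        raise
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _run_stage(stage: str, cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    seed = stage_seed(cfg.seed, stage)
    if stage == "simulate":
        scfg = SyntheticConfig(**{**cfg.synthetic, "seed": seed})
        cohort = generate_cohort(scfg)
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        for ts in cohort.timeseries:
            io.write_timeseries(ts, ts_dir / f"{ts.subject_id}.csv")
        pheno_path = out / "phenotypes.csv"
        cohort.pheno.to_csv(pheno_path, index=False)
        truth_path = out / "truth.json"
        io.write_json(cohort.truth, truth_path)
        state["timeseries"] = cohort.timeseries
        state["pheno"] = cohort.pheno
        return [pheno_path, truth_path]

    if stage == "connectivity":
        ts_list = state.get("timeseries") or io.read_timeseries_dir(out / "timeseries")
        state["connectivity"] = [compute_connectivity(ts) for ts in ts_list]
        conn_dir = out / "connectivity"
        conn_dir.mkdir(exist_ok=True)
        paths = []
        for cm in state["connectivity"]:
            p = conn_dir / f"{cm.subject_id}.csv"
            io.write_matrix(cm, p)
            paths.append(p)
        return paths[:3]  # manifest samples the first few digests

    if stage == "metrics":
        frames = []
        children = np.random.SeedSequence(seed).spawn(len(state["connectivity"]))
        for cm, child in zip(state["connectivity"], children):
            adjs = cost_sweep(cm, cfg.costs)
            sub_seed = int(child.generate_state(1)[0] % 2**31)
            frames.append(metric_sweep(adjs, n_iter=cfg.null_iters, seed=sub_seed))
        metrics = pd.concat(frames, ignore_index=True)
        path = out / "metrics.csv"
        io.write_metrics(metrics, path)
        state["metrics"] = metrics
        return [path]

    if stage == "summaries":
        meta = load_roi_metadata()
        pheno = state.get("pheno")
        if pheno is None:
            pheno = pd.read_csv(out / "phenotypes.csv")
        metrics = state.get("metrics")
        if metrics is None:
            metrics = io.read_metrics(out / "metrics.csv")
        # the cohort defines the included ROI set; restrict the atlas
        # metadata to it (mirrors the study's field-of-view inclusion)
        present = set(metrics.loc[metrics["roi_id"] != "", "roi_id"])
        meta = meta[meta["roi_id"].isin(present)]
        summaries = summarize_subnetworks(metrics, meta)
        spath = out / "subnetwork_summaries.csv"
        summaries.to_csv(spath, index=False)
        pheno = derive_phenotypes(pheno)
        ppath = out / "phenotypes_derived.csv"
        pheno.to_csv(ppath, index=False)
        state["summaries"] = summaries
        state["pheno"] = pheno
        return [spath, ppath]

    if stage == "stats":
        pheno_path = out / "phenotypes_derived.csv"
        pheno = state.get("pheno")
        if pheno is None:
            if not pheno_path.exists():
                raise FileNotFoundError(f"phenotype file missing: {pheno_path}")
            pheno = pd.read_csv(pheno_path)
        metrics = state.get("metrics")
        if metrics is None:
            metrics = io.read_metrics(out / "metrics.csv")
        if cfg.target == "whole_network":
            wide = metric_wide(metrics, cfg.metric)
        else:
            wide = target_wide(state["summaries"], cfg.target)
        ph = pheno.set_index("subject_id").loc[wide.index].reset_index()
        effects = rm_ancova(
            wide, ph, between="abeta_positive",
            predictor=cfg.predictor, covariates=cfg.covariates,
        )
        scan = interaction_scan(
            wide, ph, predictor=cfg.predictor,
            covariates=cfg.covariates, method=cfg.multiplicity,
        )
        mean_metric = wide.mean(axis=1).to_numpy()
        ph_idx = pheno.set_index("subject_id").loc[wide.index]
        corr = group_partial_correlations(
            mean_metric, ph_idx, predictor=cfg.predictor, covariates=cfg.covariates
        )
        report = {
            "metric": cfg.metric,
            "target": cfg.target,
            "effects": [dataclasses.asdict(e) for e in effects],
            "group_partial_correlations": corr.to_dict(orient="records"),
        }
        rpath = out / "stats_report.json"
        io.write_json(report, rpath)
        spath = out / "interaction_scan.csv"
        scan.to_csv(spath, index=False)
        return [rpath, spath]

    raise ValueError(f"unknown stage {stage!r}")
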