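"""End-to-end orchestration: evaluate a score table, audit for ligand-only
bias, and write a reproducible result bundle.

All randomness (bootstrap resampling, model seeds) flows from the single
``RunConfig.seed``; two runs with equal configs produce byte-identical CSVs.
Each bundle carries a ``manifest.json`` recording the verbatim config, its
hash, the seed and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .io_model import Benchmark, read_score_table, write_results
from .metrics import MetricResult, bootstrap_interval, summarize_benchmark
from .metrics import enrichment_factor, normalized_ef, roc_auc
from .pose_eval import build_crossdock_tasks, good_pose_fraction, sampling_ceiling
from .protocols import PROTOCOLS, predictions_to_vectors

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_evaluation", "run_bias_audit"]

_POINT_METRICS = {"auc": lambda y, s, a: roc_auc(y, s),
                  "ef": enrichment_factor, "nef": normalized_ef}


@dataclass
class RunConfig:
    """Configuration for one evaluation run."""

    scores: str
    out_dir: str
    channels: list[str] | None = None          # None = every channel in the table
    protocols: list[str] = field(default_factory=lambda: ["best_pose"])
    metrics: list[str] = field(default_factory=lambda: ["auc", "ef", "nef"])
    alpha: float = 0.01
    n_boot: int = 1000                          # 0 disables bootstrap CIs
    level: float = 0.95
    seed: int = 0
    pose_channel: str | None = None             # needed by cnn_vs / affinity_at_best_pose
    affinity_channel: str | None = None
    cognates: str | None = None                 # enables the pose-eval block
    pose_ranks: list[int] = field(default_factory=lambda: [1, 3, 5])
    rmsd_threshold: float = 2.0
    log_level: str = "INFO"

    def validate(self) -> None:
        bad = [p for p in self.protocols if p not in PROTOCOLS]
        if bad:
            raise ConfigError(f"unknown protocol(s) {bad}; expected {sorted(PROTOCOLS)}")
        bad = [m for m in self.metrics if m not in _POINT_METRICS]
        if bad:
            raise ConfigError(f"unknown metric(s) {bad}; expected {sorted(_POINT_METRICS)}")
        if not self.protocols:
            raise ConfigError("protocols list must be non-empty")
        two_channel = {"cnn_vs", "affinity_at_best_pose"}
        if two_channel & set(self.protocols) and not (self.pose_channel and self.affinity_channel):
            raise ConfigError(
                "protocols cnn_vs/affinity_at_best_pose require pose_channel and affinity_channel")


def _manifest(cfg, extra: dict | None = None) -> dict:
    cfg_dict = dataclasses.asdict(cfg)
    blob = json.dumps(cfg_dict, sort_keys=True)
    return {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": cfg.seed,
        "package_version": __version__,
        **(extra or {}),
    }


def _method_predictions(table, cfg: RunConfig):
    """Yield (method_name, channel, predictions) per configured protocol."""
    channels = cfg.channels or sorted(table.channels)
    for proto in cfg.protocols:
        if proto in ("cnn_vs", "affinity_at_best_pose"):
            fn = PROTOCOLS[proto]
            yield (f"{proto}", cfg.pose_channel,
                   fn(table, cfg.pose_channel, cfg.affinity_channel, method=proto))
        else:
            for ch in channels:
                yield (f"{ch}:{proto}", ch, PROTOCOLS[proto](table, ch, method=f"{ch}:{proto}"))


def run_evaluation(cfg: RunConfig, benchmark: Benchmark | None = None) -> dict:
    """Evaluate every configured (protocol, channel) on every target.

    Writes ``metrics.csv`` (per-target results with bootstrap CIs),
    ``summary.csv`` (medians with best-method flags and Mann-Whitney p-values
    against the best), optionally ``pose_eval.csv``, and ``manifest.json``.
    Returns the bundle as a dict of DataFrames/paths.
    """
    cfg.validate()
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()

    bench = benchmark if benchmark is not None else read_score_table(cfg.scores)
    rng = np.random.default_rng(cfg.seed)

    results: list[MetricResult] = []
    for table in bench:
        for method, channel, preds in _method_predictions(table, cfg):
            labels, scores, _ = predictions_to_vectors(table, preds)
            for metric in cfg.metrics:
                value = _POINT_METRICS[metric](labels, scores, cfg.alpha)
                ci_lo = ci_hi = n_boot = None
                if cfg.n_boot:
                    ci_lo, ci_hi = bootstrap_interval(
                        labels, scores, metric, cfg.alpha,
                        n_boot=cfg.n_boot, level=cfg.level, seed=rng)
                    # percentile CIs from finite resamples may sit a hair off
                    # the point estimate; widen to bracket it
                    ci_lo, ci_hi = min(ci_lo, value), max(ci_hi, value)
                    n_boot = cfg.n_boot
                results.append(MetricResult(
                    target_id=table.target_id, method=method, metric=metric,
                    value=value, alpha=None if metric == "auc" else cfg.alpha,
                    ci_low=ci_lo, ci_high=ci_hi, n_boot=n_boot, channel=channel))
    write_results(results, out / "metrics.csv")
    summary = summarize_benchmark(results, statistic="median")
    summary.to_csv(out / "summary.csv", index=False)
    logger.info("evaluation: %d results in %.1fs", len(results), time.monotonic() - t0)

    bundle = {"metrics": results, "summary": summary, "out_dir": out}

    if cfg.cognates:
        poses = pd.read_csv(cfg.scores)
        if "rmsd" not in poses.columns:
            raise ConfigError("pose-eval requested but score table has no rmsd column")
        cmap_df = pd.read_csv(cfg.cognates)
        cmap = dict(zip(cmap_df.iloc[:, 0].astype(str), cmap_df.iloc[:, 1].astype(str)))
        tasks = build_crossdock_tasks(poses, cmap)
        rows = []
        score_cols = [c for c in poses.columns
                      if c not in ("target", "compound", "receptor", "pose_rank", "rmsd", "label")]
        for ch in (cfg.channels or score_cols):
            fracs = good_pose_fraction(tasks, ch, cfg.pose_ranks, cfg.rmsd_threshold)
            for rank, frac in fracs.items():
                rows.append({"channel": ch, "rank": rank, "good_pose_fraction": frac})
        ceiling = sampling_ceiling(tasks, cfg.rmsd_threshold)
        rows.append({"channel": "(any)", "rank": 0, "good_pose_fraction": ceiling})
        pose_df = pd.DataFrame(rows)
        pose_df.to_csv(out / "pose_eval.csv", index=False)
        bundle["pose_eval"] = pose_df

    manifest = _manifest(cfg, {"n_targets": len(bench), "stage": "evaluate"})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return bundle


@dataclass
class BiasAuditConfig:
    """Configuration for a ligand-only bias audit."""

    train: str                                   # CSV: compound index, features..., pk column
    bench: dict[str, str] = field(default_factory=dict)  # target -> descriptor CSV with label col
    out_dir: str = "audit_out"
    families: list[str] = field(default_factory=lambda: ["lasso", "random_forest"])
    metrics: list[str] = field(default_factory=lambda: ["nef", "auc"])
    alpha: float = 0.01
    cv_folds: int = 5
    seed: int = 0

    def validate(self) -> None:
        from .baselines import FAMILIES
        if not self.families:
            raise ConfigError("families list must be non-empty")
        bad = [f for f in self.families if f not in FAMILIES]
        if bad:
            raise ConfigError(f"unknown model family(ies) {bad}; expected {FAMILIES}")
        if not self.bench:
            raise ConfigError("bench mapping (target -> descriptor CSV) must be non-empty")


def run_bias_audit(cfg: BiasAuditConfig) -> dict:
    """Fit each baseline family to the affinity training table, screen every
    benchmark target with it, and report per-target metrics plus the
    per-target maximum over configurations (the ligand-only ceiling).
    """
    from .baselines import BaselineModelSpec, best_baseline_per_target, fit_baseline, \
        screen_with_baseline
    from .metrics import as_binary_labels

    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    train = pd.read_csv(cfg.train, index_col=0)
    if "pk" not in train.columns:
        raise ConfigError("training table needs a 'pk' column")
    pk = train.pop("pk")

    rows = []
    for family in cfg.families:
        model = fit_baseline(train, pk, BaselineModelSpec(family=family,
                                                          cv_folds=cfg.cv_folds,
                                                          seed=cfg.seed))
        for target, path in sorted(cfg.bench.items()):
            bench_df = pd.read_csv(path, index_col=0)
            labels = as_binary_labels(bench_df.pop("label").to_numpy())
            preds = screen_with_baseline(model, bench_df)
            for metric in cfg.metrics:
                value = _POINT_METRICS[metric](labels, preds.to_numpy(), cfg.alpha)
                rows.append({"target": target, "config": family,
                             "metric": metric, "value": value})
    results = pd.DataFrame(rows)
    results.to_csv(out / "bias_audit.csv", index=False)
    best = best_baseline_per_target(results, metric=cfg.metrics[0])
    best.to_csv(out / "bias_audit_best.csv", index=False)
    manifest = _manifest(cfg, {"stage": "bias_audit"})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return {"results": results, "best": best, "out_dir": out}
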