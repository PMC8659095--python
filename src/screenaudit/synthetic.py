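"""Synthetic screening benchmarks with known ground truth.

Every pipeline stage gets a parameter-recovery test from data generated here;
no external benchmark archive is needed.  The generative models:

* **Scores** — equal-variance binormal: for a method with separation ``d``,
  active compounds score ``Normal(d, 1)`` and inactives ``Normal(0, 1)``.
  The model's ROC-AUC has the closed form ``Phi(d / sqrt(2))``, which is the
  recovery oracle.  Per-compound pose ensembles are built so that the best
  pose carries the compound-level score (lower-ranked poses receive strictly
  lower scores), hence best-pose aggregation reconstructs the binormal draw.
* **Pose quality** — each cross-docking task has a good pose (RMSD drawn from
  ``Uniform(0, 2)``) with probability ``p_good_pose``; other poses draw RMSD
  from ``Uniform(2, 10)``.  With ``score_rmsd_coupling = 1`` the good pose
  always receives the top score; with coupling 0 its score rank is uniform.
  The planted rank of each good pose is recorded in the truth sidecar.
* **Descriptors** — independent standard-normal features; benchmark actives
  are shifted by ``active_shift`` along the (unit) weight vector that also
  generates training affinities ``pK = 6 + w.x + Normal(0, sigma)``, so
  ligand-only baselines can exploit exactly the planted bias and nothing else.
* **Fingerprints** — random bit vectors at a given density; benchmark actives
  are bit-flipped copies of training-pool members at ``flip_rate``, making
  the average-max-Tanimoto similarity statistic controllable (flip_rate 0
  gives verbatim copies, similarity 1).

Everything is driven by one seed; identical configs give byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError
from .io_model import Benchmark, ScoreChannel, ScreenTable

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_benchmark",
           "generate_pose_ensembles", "write_bundle"]


@dataclass
class SyntheticConfig:
    """Generating parameters for a synthetic benchmark.

    Defaults emulate a DUD-E-like target: ~5% active rate, nine poses per
    compound (typical docking output), and method separations spanning a
    strong CNN-like scorer (AUC 0.8), an empirical-scoring-function-like
    baseline (AUC ~0.7) and a no-signal control.
    """

    n_targets: int = 10
    n_actives: int = 250
    n_inactives: int = 4750
    #: (method name, separation d); active scores ~ N(d, 1), inactive ~ N(0, 1)
    methods: tuple = (("cnn", 1.19), ("empirical", 0.74), ("null", 0.0))
    n_receptors: int = 1
    poses_per_compound: int = 9
    p_good_pose: float = 0.6
    score_rmsd_coupling: float = 1.0
    descriptor_dim: int = 6
    active_shift: float = 0.0
    n_train: int = 2000
    train_noise_sd: float = 1.0
    fingerprint_bits: int = 2048
    n_pool: int = 500
    bit_density: float = 0.05
    flip_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_good_pose", "score_rmsd_coupling", "bit_density", "flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_targets", "n_actives", "n_inactives", "poses_per_compound",
                     "n_receptors", "descriptor_dim", "n_train", "fingerprint_bits", "n_pool"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for mname, d in self.methods:
            if d < 0:
                raise ConfigError(f"methods: separation for {mname!r} must be >= 0, got {d}")
        if self.train_noise_sd <= 0:
            raise ConfigError(f"train_noise_sd must be > 0, got {self.train_noise_sd}")
        if self.active_shift < 0:
            raise ConfigError(f"active_shift must be >= 0, got {self.active_shift}")


@dataclass
class SyntheticTruth:
    """Ground truth the generator planted, for recovery tests."""

    expected_auc: dict[str, float]          # method -> Phi(d / sqrt(2))
    separations: dict[str, float]           # method -> d
    active_shift: float
    weights: list[float]                    # training affinity weight vector w
    flip_rate: float
    p_good_pose: float
    score_rmsd_coupling: float
    planted_good_ranks: dict[str, int] = field(default_factory=dict)  # task key -> score rank

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def expected_auc(d: float) -> float:
    """Closed-form ROC-AUC of the equal-variance binormal model."""
    return float(norm.cdf(d / np.sqrt(2.0)))


def _compound_ids(cfg: SyntheticConfig) -> tuple[list[str], np.ndarray]:
    ids = [f"act{i:05d}" for i in range(cfg.n_actives)] + \
          [f"dec{i:05d}" for i in range(cfg.n_inactives)]
    labels = np.concatenate([np.ones(cfg.n_actives, int), np.zeros(cfg.n_inactives, int)])
    return ids, labels


def generate_benchmark(cfg: SyntheticConfig) -> tuple[Benchmark, dict, SyntheticTruth]:
    """Generate a full synthetic bundle.

    Returns ``(benchmark, extras, truth)`` where ``extras`` holds the
    descriptor tables, fingerprints and training table:

    - ``descriptors_train``: DataFrame (compound x features) + ``train_pk`` Series
    - ``descriptors_bench``: dict target -> DataFrame with matching features
    - ``fp_pool`` / ``fp_actives``: dict name -> bit array
    - ``bench_labels``: dict target -> dict compound -> label
    """
    cfg.validate()
    root = np.random.default_rng(cfg.seed)
    # independent child streams so adding one block never perturbs another
    rng_scores, rng_desc, rng_fp = [np.random.default_rng(s)
                                    for s in np.random.SeedSequence(cfg.seed).spawn(3)]

    ids, labels = _compound_ids(cfg)
    n = len(ids)
    channels = [ScoreChannel(m, "higher_better", "generic") for m, _ in cfg.methods]
    receptors = [f"r{j}" for j in range(cfg.n_receptors)]

    targets: dict[str, ScreenTable] = {}
    for t in range(cfg.n_targets):
        tid = f"T{t:03d}"
        # per-compound binormal draws, one column per method
        comp_scores = {m: rng_scores.normal(0.0, 1.0, n) + d * labels
                       for m, d in cfg.methods}
        # expand to poses: best pose carries the compound score, the rest are
        # strictly lower (subtract positive offsets), receptors cycle round-robin
        k = cfg.poses_per_compound
        rows = {
            "compound": np.repeat(ids, k),
            "receptor": np.tile([receptors[j % cfg.n_receptors] for j in range(k)], n),
            "pose_rank": np.tile(np.arange(1, k + 1), n),
        }
        offsets = np.concatenate([np.zeros((n, 1)),
                                  np.cumsum(rng_scores.exponential(0.3, (n, k - 1)), axis=1)],
                                 axis=1) if k > 1 else np.zeros((n, 1))
        for m, _ in cfg.methods:
            rows[m] = (comp_scores[m][:, None] - offsets).ravel()
        poses = pd.DataFrame(rows)
        lab_map = {c: ("active" if l else "inactive") for c, l in zip(ids, labels)}
        targets[tid] = ScreenTable(tid, poses, lab_map, channels)

    # descriptor block: training pool + per-target benchmark tables
    w = rng_desc.normal(0.0, 1.0, cfg.descriptor_dim)
    w /= np.linalg.norm(w)
    feat_names = [f"f{j}" for j in range(cfg.descriptor_dim)]
    x_train = rng_desc.normal(0.0, 1.0, (cfg.n_train, cfg.descriptor_dim))
    pk = 6.0 + x_train @ w + rng_desc.normal(0.0, cfg.train_noise_sd, cfg.n_train)
    train_ids = [f"trn{i:05d}" for i in range(cfg.n_train)]
    descriptors_train = pd.DataFrame(x_train, index=pd.Index(train_ids, name="compound"),
                                     columns=feat_names)
    train_pk = pd.Series(pk, index=descriptors_train.index, name="pk")

    descriptors_bench = {}
    for tid in targets:
        x = rng_desc.normal(0.0, 1.0, (n, cfg.descriptor_dim))
        x += cfg.active_shift * np.outer(labels, w)
        descriptors_bench[tid] = pd.DataFrame(
            x, index=pd.Index(ids, name="compound"), columns=feat_names)

    # fingerprint block: actives are bit-flipped pool copies
    pool_bits = rng_fp.random((cfg.n_pool, cfg.fingerprint_bits)) < cfg.bit_density
    fp_pool = {f"pool{i:05d}": pool_bits[i] for i in range(cfg.n_pool)}
    parents = rng_fp.integers(0, cfg.n_pool, cfg.n_actives)
    flips = rng_fp.random((cfg.n_actives, cfg.fingerprint_bits)) < cfg.flip_rate
    fp_actives = {f"act{i:05d}": np.logical_xor(pool_bits[parents[i]], flips[i])
                  for i in range(cfg.n_actives)}

    truth = SyntheticTruth(
        expected_auc={m: expected_auc(d) for m, d in cfg.methods},
        separations=dict(cfg.methods),
        active_shift=cfg.active_shift,
        weights=[float(v) for v in w],
        flip_rate=cfg.flip_rate,
        p_good_pose=cfg.p_good_pose,
        score_rmsd_coupling=cfg.score_rmsd_coupling,
    )
    extras = {
        "descriptors_train": descriptors_train,
        "train_pk": train_pk,
        "descriptors_bench": descriptors_bench,
        "fp_pool": fp_pool,
        "fp_actives": fp_actives,
        "bench_labels": {tid: dict(targets[tid].labels) for tid in targets},
    }
    return Benchmark("synthetic", targets), extras, truth


def generate_pose_ensembles(cfg: SyntheticConfig) -> tuple[pd.DataFrame, dict[str, str], SyntheticTruth]:
    """Generate a cross-docking pose table with planted good-pose ranks.

    Returns ``(pose_table, cognate_map, truth)``.  Each target contributes
    ``n_receptors`` crystal ligands (one cognate receptor each), cross-docked
    into every non-cognate receptor; ``truth.planted_good_ranks`` maps
    ``"target/ligand/receptor"`` to the score rank (1-based) the good pose was
    planted at, or 0 when the task has no good pose.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(4)[3])
    k = cfg.poses_per_compound
    rows = []
    planted: dict[str, int] = {}
    cognate_map: dict[str, str] = {}
    for t in range(cfg.n_targets):
        tid = f"T{t:03d}"
        receptors = [f"{tid}_r{j}" for j in range(cfg.n_receptors)]
        for j, cognate in enumerate(receptors):
            lig = f"{tid}_lig{j}"
            cognate_map[lig] = cognate
            for rec in receptors:
                if rec == cognate:
                    continue
                has_good = rng.random() < cfg.p_good_pose
                # score rank of the good pose: 1 under full coupling, else uniform
                if has_good:
                    good_rank = 1 if rng.random() < cfg.score_rmsd_coupling \
                        else int(rng.integers(1, k + 1))
                else:
                    good_rank = 0
                scores = -np.sort(-rng.normal(0.0, 1.0, k))  # descending
                rmsd = rng.uniform(2.0, 10.0, k)
                if has_good:
                    rmsd[good_rank - 1] = rng.uniform(0.0, 2.0)
                planted[f"{tid}/{lig}/{rec}"] = good_rank
                for p in range(k):
                    rows.append((tid, lig, rec, p + 1, scores[p], rmsd[p]))
    table = pd.DataFrame(rows, columns=["target", "compound", "receptor",
                                        "pose_rank", "score", "rmsd"])
    truth = SyntheticTruth(
        expected_auc={}, separations={}, active_shift=0.0, weights=[],
        flip_rate=cfg.flip_rate, p_good_pose=cfg.p_good_pose,
        score_rmsd_coupling=cfg.score_rmsd_coupling, planted_good_ranks=planted)
    return table, cognate_map, truth


def write_bundle(out_dir: str | Path, cfg: SyntheticConfig) -> Path:
    """Generate and write the full synthetic bundle to ``out_dir``.

    Files: scores.csv (per-pose score table), descriptors_train.csv (features
    + pk), descriptors_bench_<target>.csv, fp_pool.csv, fp_actives.csv,
    poses.csv + cognates.csv (cross-docking block), truth.json, config.json.
    """
    from .similarity import write_fingerprints

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bench, extras, truth = generate_benchmark(cfg)

    frames = []
    for table in bench:
        df = table.poses.copy()
        df.insert(0, "target", table.target_id)
        df["label"] = df["compound"].map(table.labels)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(out / "scores.csv", index=False)

    train = extras["descriptors_train"].copy()
    train["pk"] = extras["train_pk"]
    train.to_csv(out / "descriptors_train.csv")
    for tid, df in extras["descriptors_bench"].items():
        labelled = df.copy()
        labelled["label"] = pd.Series(extras["bench_labels"][tid])
        labelled.to_csv(out / f"descriptors_bench_{tid}.csv")
    write_fingerprints(extras["fp_pool"], out / "fp_pool.csv")
    write_fingerprints(extras["fp_actives"], out / "fp_actives.csv")

    poses, cognates, pose_truth = generate_pose_ensembles(cfg)
    poses.to_csv(out / "poses.csv", index=False)
    pd.DataFrame(sorted(cognates.items()), columns=["ligand", "receptor"]).to_csv(
        out / "cognates.csv", index=False)

    truth.planted_good_ranks = pose_truth.planted_good_ranks
    (out / "truth.json").write_text(truth.to_json() + "\n")
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=1, sort_keys=True) + "\n")
    return out
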