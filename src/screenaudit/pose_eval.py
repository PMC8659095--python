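"""Cross-docking pose-prediction evaluation.

A cross-docking task docks a crystal ligand into a *non-cognate* receptor
template of the same target (a structure solved with a different ligand) and
asks whether the scoring function ranks a good pose — RMSD ≤ 2 Å from the
reference — near the top.  Two summaries are computed:

* ``good_pose_fraction``: for each rank cutoff n, the fraction of tasks whose
  top-n poses (by a score channel) contain at least one good pose, averaged
  per target first and then across targets (targets weigh equally regardless
  of how many ligand/template pairs they contribute).
* ``sampling_ceiling``: the fraction of tasks with *any* good pose sampled,
  i.e. the best performance any re-ranking of the sampled poses could reach.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError

logger = logging.getLogger(__name__)

__all__ = ["CrossdockTask", "build_crossdock_tasks", "good_pose_fraction", "sampling_ceiling"]


@dataclass
class CrossdockTask:
    """Poses of one crystal ligand docked into one non-cognate receptor template."""

    target_id: str
    ligand_id: str
    receptor_id: str
    poses: pd.DataFrame  # pose_rank, rmsd, + score channels

    def __post_init__(self) -> None:
        if "rmsd" not in self.poses.columns or self.poses["rmsd"].isna().any():
            raise IntegrityError(
                f"task ({self.ligand_id}, {self.receptor_id}): rmsd required on every pose")


def build_crossdock_tasks(
    poses: pd.DataFrame,
    cognate_map: Mapping[str, str],
) -> list[CrossdockTask]:
    """Split a pose table into per-(ligand, non-cognate receptor) tasks.

    ``poses`` needs columns target, compound (the crystal ligand id), receptor,
    pose_rank, rmsd and score channels.  ``cognate_map`` gives each ligand's
    own receptor; (ligand, cognate receptor) pairs are excluded.
    """
    for col in ("target", "compound", "receptor", "pose_rank", "rmsd"):
        if col not in poses.columns:
            raise IntegrityError(f"pose table lacks column {col!r}")
    missing = set(poses["compound"]) - set(cognate_map)
    if missing:
        raise IntegrityError(f"ligands missing from cognate map: {sorted(missing)[:5]}")
    tasks = []
    for (tid, lig, rec), sub in poses.groupby(["target", "compound", "receptor"], sort=True):
        if cognate_map[lig] == rec:
            continue
        tasks.append(CrossdockTask(str(tid), str(lig), str(rec),
                                   sub.drop(columns=["target", "compound", "receptor"])
                                      .reset_index(drop=True)))
    return tasks


def _first_good_rank(task: CrossdockTask, channel: str, threshold: float) -> float:
    """1-based position of the first good pose when ordered by the score channel.

    Ties in score are broken by the original pose_rank. Returns inf when the
    task has no good pose (or no poses at all).
    """
    df = task.poses
    if len(df) == 0:
        logger.warning("task (%s, %s): zero poses, counted as failure",
                       task.ligand_id, task.receptor_id)
        return np.inf
    if channel not in df.columns:
        raise IntegrityError(f"channel {channel!r} absent from task "
                             f"({task.ligand_id}, {task.receptor_id})")
    order = np.lexsort((df["pose_rank"].to_numpy(), -df[channel].to_numpy(dtype=float)))
    good = df["rmsd"].to_numpy(dtype=float)[order] <= threshold
    hits = np.flatnonzero(good)
    return float(hits[0] + 1) if hits.size else np.inf


def good_pose_fraction(
    tasks: Sequence[CrossdockTask],
    channel: str,
    ranks: Sequence[int] = (1, 3, 5),
    threshold: float = 2.0,
) -> dict[int, float]:
    """Fraction of tasks with a good pose among the top-n scored poses, per rank n.

    Per-target fractions are averaged first, then averaged across targets
    (unweighted).  Fractions are non-decreasing in n and bounded above by
    :func:`sampling_ceiling`.
    """
    if threshold <= 0:
        raise DomainError(f"threshold must be positive, got {threshold}")
    ranks = list(ranks)
    if ranks != sorted(ranks) or any(r < 1 for r in ranks):
        raise DomainError(f"ranks must be ascending positive integers, got {ranks}")
    if not tasks:
        raise DomainError("no tasks to evaluate")
    rows = [(t.target_id, _first_good_rank(t, channel, threshold)) for t in tasks]
    df = pd.DataFrame(rows, columns=["target", "first_good"])
    out = {}
    for n in ranks:
        per_target = df.groupby("target")["first_good"].apply(lambda fg: float((fg <= n).mean()))
        out[int(n)] = float(per_target.mean())
    return out


def sampling_ceiling(tasks: Sequence[CrossdockTask], threshold: float = 2.0) -> float:
    """Fraction of tasks with any sampled pose at RMSD ≤ threshold (score ignored).

    Per-target averaged like :func:`good_pose_fraction`, so it upper-bounds the
    rank fractions at every rank.
    """
    if threshold <= 0:
        raise DomainError(f"threshold must be positive, got {threshold}")
    if not tasks:
        raise DomainError("no tasks to evaluate")
    rows = [(t.target_id,
             bool((t.poses["rmsd"].to_numpy(dtype=float) <= threshold).any()) if len(t.poses) else False)
            for t in tasks]
    df = pd.DataFrame(rows, columns=["target", "has_good"])
    return float(df.groupby("target")["has_good"].mean().mean())
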