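"""Aggregation protocols: from per-pose, per-receptor scores to one prediction
per (target, compound).

The standard screening protocol takes a method's best score over every pose
and every receptor as the compound's prediction (``best_pose``).  Its mirror
(``worst_pose``) takes the lowest-scored pose instead and is used as a
pose-sensitivity probe: a method whose ranking survives being fed its worst
poses is likely exploiting ligand-only information rather than protein-ligand
interactions.  Two score-combination protocols merge a pose probability with a
predicted affinity: the per-pose product (``cnn_vs``) and the affinity of the
best-pose-scored pose (``affinity_at_best_pose``).

All scores are assumed canonical (higher is better); poses and receptors are
treated symmetrically (a flat max/min over all poses of the compound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError
from .io_model import ScreenTable

__all__ = [
    "CompoundPrediction", "aggregate_best", "aggregate_worst",
    "product_score", "product_score_predictions", "affinity_at_best_pose",
    "PROTOCOLS", "predictions_to_vectors",
]


@dataclass(frozen=True)
class CompoundPrediction:
    """One method's prediction for one (target, compound); higher = more likely active."""

    target_id: str
    compound_id: str
    method: str
    value: float


def _check_channel(table: ScreenTable, channel: str) -> None:
    if channel not in table.channels:
        raise IntegrityError(
            f"channel {channel!r} not registered on target {table.target_id!r} "
            f"(have {sorted(table.channels)})"
        )


def _aggregate(table: ScreenTable, channel: str, how: str, method: str) -> list[CompoundPrediction]:
    _check_channel(table, channel)
    agg = table.poses.groupby("compound", sort=True)[channel].agg(how)
    return [CompoundPrediction(table.target_id, str(c), method, float(v))
            for c, v in agg.items()]


def aggregate_best(table: ScreenTable, channel: str,
                   method: str | None = None) -> list[CompoundPrediction]:
    """Best (maximum) score over all poses and receptors per compound."""
    return _aggregate(table, channel, "max", method or f"{channel}:best_pose")


def aggregate_worst(table: ScreenTable, channel: str,
                    method: str | None = None) -> list[CompoundPrediction]:
    """Worst (minimum) score over all poses and receptors per compound."""
    return _aggregate(table, channel, "min", method or f"{channel}:worst_pose")


def product_score(pose_prob: float, affinity_pk: float) -> float:
    """Per-pose combined score: pose probability times the predicted affinity.

    Negative predicted affinities are clipped to 0 before multiplying so the
    product stays on a higher-is-better scale.
    """
    if not 0.0 <= pose_prob <= 1.0:
        raise DomainError(f"pose probability must lie in [0, 1], got {pose_prob}")
    return pose_prob * max(affinity_pk, 0.0)


def product_score_predictions(
    table: ScreenTable,
    pose_channel: str = "pose",
    affinity_channel: str = "affinity",
    method: str | None = None,
) -> list[CompoundPrediction]:
    """The combined product score, computed per pose and then best-pose aggregated."""
    _check_channel(table, pose_channel)
    _check_channel(table, affinity_channel)
    if table.channels[pose_channel].kind != "pose_prob":
        pp = table.poses[pose_channel].to_numpy(dtype=float)
        if ((pp < 0) | (pp > 1)).any():
            raise DomainError(f"channel {pose_channel!r} has values outside [0, 1]")
    prod = table.poses[pose_channel].to_numpy(dtype=float) * np.maximum(
        table.poses[affinity_channel].to_numpy(dtype=float), 0.0)
    agg = pd.Series(prod, index=table.poses["compound"]).groupby(level=0, sort=True).max()
    name = method or f"{pose_channel}*{affinity_channel}:cnn_vs"
    return [CompoundPrediction(table.target_id, str(c), name, float(v))
            for c, v in agg.items()]


def affinity_at_best_pose(
    table: ScreenTable,
    pose_channel: str = "pose",
    affinity_channel: str = "affinity",
    method: str | None = None,
) -> list[CompoundPrediction]:
    """Predicted affinity of the pose with the best pose score, per compound.

    Ties in pose score are broken by lower pose_rank, then lexicographic
    receptor id, so the output is deterministic.
    """
    _check_channel(table, pose_channel)
    _check_channel(table, affinity_channel)
    for ch in (pose_channel, affinity_channel):
        if table.poses[ch].isna().any():
            raise IntegrityError(f"channel {ch!r} missing on some poses")
    df = table.poses.sort_values(
        by=[pose_channel, "pose_rank", "receptor"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    picked = df.groupby("compound", sort=True).first()
    name = method or f"{affinity_channel}@best_{pose_channel}"
    return [CompoundPrediction(table.target_id, str(c), name, float(row[affinity_channel]))
            for c, row in picked.iterrows()]


#: protocol registry for config/CLI use
PROTOCOLS = {
    "best_pose": aggregate_best,
    "worst_pose": aggregate_worst,
    "cnn_vs": product_score_predictions,
    "affinity_at_best_pose": affinity_at_best_pose,
}


def predictions_to_vectors(
    table: ScreenTable,
    predictions: list[CompoundPrediction],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align predictions with the table's labels for metric computation.

    Returns ``(labels, scores, compound_ids)`` over every labelled compound.
    Compounds without a prediction (no docked pose) are ranked last with a
    score of -inf and a logged warning — the conservative screening reading.
    """
    import logging

    values = {p.compound_id: p.value for p in predictions}
    ids = np.array(sorted(table.labels), dtype=object)
    labels = np.array([1 if table.labels[c] == "active" else 0 for c in ids])
    scores = np.array([values.get(c, -np.inf) for c in ids], dtype=float)
    n_missing = int(np.isneginf(scores).sum())
    if n_missing:
        logging.getLogger(__name__).warning(
            "target %s: %d compounds without predictions ranked last",
            table.target_id, n_missing)
    return labels, scores, ids
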