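"""Ranking and early-recognition statistics with uncertainty.

The screening metrics used throughout:

* **AUC** — area under the ROC curve, equal to the probability that a randomly
  chosen active outranks a randomly chosen inactive, with half credit for
  ties (midrank convention).  1.0 is a perfect ranking, 0.5 random.
* **EFα** — enrichment factor at fraction α: the active rate among the top
  ``k = ceil(α·N)`` compounds divided by the library-wide active rate.
* **NEFα** — EFα divided by the best EFα achievable for the library's
  active/total counts, so 1.0 means as many actives as possible sit in the
  top fraction and 0 means none do.  NEF is comparable across benchmarks
  whose active rates differ; raw EF is not.

Uncertainty is quantified with a stratified percentile bootstrap (actives and
inactives resampled separately, preserving class counts) and method
comparisons across targets use the two-sided Mann-Whitney U rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, IntegrityError, UndefinedMetricError

__all__ = [
    "MetricResult", "ComparisonResult", "roc_auc", "enrichment_factor",
    "max_enrichment_factor", "normalized_ef", "bootstrap_interval",
    "compare_distributions", "summarize_benchmark", "significant_win_count",
    "as_binary_labels",
]


@dataclass
class MetricResult:
    """A named metric value for (target, method) with an optional bootstrap CI."""

    target_id: str
    method: str
    metric: str  # auc | ef | nef
    value: float
    alpha: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None
    channel: str | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.value + 1e-12 and self.value - 1e-12 <= self.ci_high):
                raise IntegrityError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket value {self.value}"
                )


@dataclass
class ComparisonResult:
    """Two-sided Mann-Whitney comparison of two per-target metric distributions."""

    method_a: str
    method_b: str
    metric: str
    p_value: float
    n_targets: int


def as_binary_labels(labels: Sequence) -> np.ndarray:
    """Coerce labels (bool, 0/1, 'active'/'inactive') to a 0/1 integer array."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        out = np.fromiter((1 if str(v).lower() in ("1", "active", "true") else 0 for v in arr),
                          dtype=int, count=arr.size)
        return out
    return arr.astype(int)


def _validate_two_class(labels: np.ndarray, scores: np.ndarray) -> tuple[int, int]:
    if labels.shape != scores.shape:
        raise DomainError(f"labels and scores lengths differ: {labels.size} vs {scores.size}")
    n_act = int(labels.sum())
    n_inact = int(labels.size - n_act)
    if n_act == 0 or n_inact == 0:
        raise UndefinedMetricError(
            f"metric undefined: need both classes, got {n_act} actives / {n_inact} inactives"
        )
    return n_act, n_inact


def roc_auc(labels: Sequence, scores: Sequence) -> float:
    """ROC-AUC with midrank tie handling.

    Equals (#(active, inactive) pairs with active scored higher + ties/2)
    divided by n_act * n_inact.
    """
    labels = as_binary_labels(labels)
    scores = np.asarray(scores, dtype=float)
    n_act, n_inact = _validate_two_class(labels, scores)
    ranks = stats.rankdata(scores)  # average (midrank) method
    auc = (ranks[labels == 1].sum() - n_act * (n_act + 1) / 2) / (n_act * n_inact)
    return float(auc)


def _top_k(alpha: float, n: int) -> int:
    if not 0 < alpha <= 1:
        raise DomainError(f"alpha must be in (0, 1], got {alpha}")
    return int(math.ceil(alpha * n))


def _ranking_order(scores: np.ndarray, ids: np.ndarray | None) -> np.ndarray:
    """Indices sorted by score descending, ties broken by ascending id (deterministic)."""
    if ids is None:
        ids = np.arange(scores.size)
    # lexsort: last key is primary
    return np.lexsort((np.asarray(ids), -scores))


def enrichment_factor(labels: Sequence, scores: Sequence, alpha: float = 0.01,
                      ids: Sequence | None = None) -> float:
    """Enrichment factor at fraction ``alpha``: (a/k) / (A/N) with k = ceil(alpha*N).

    Boundary ties are broken by (score descending, compound id ascending); no
    fractional credit.  Pre-jitter scores if fractional tie handling is wanted.
    """
    labels = as_binary_labels(labels)
    scores = np.asarray(scores, dtype=float)
    n_act, _ = _validate_two_class(labels, scores)
    n = labels.size
    k = _top_k(alpha, n)
    order = _ranking_order(scores, None if ids is None else np.asarray(ids))
    a = int(labels[order[:k]].sum())
    return (a / k) / (n_act / n)


def max_enrichment_factor(n_actives: int, n_total: int, alpha: float = 0.01) -> float:
    """Best achievable EF for a library of ``n_total`` compounds with ``n_actives`` actives."""
    if n_actives <= 0:
        raise UndefinedMetricError("max EF undefined with zero actives")
    if n_actives > n_total:
        raise DomainError(f"n_actives {n_actives} > n_total {n_total}")
    k = _top_k(alpha, n_total)
    return (min(k, n_actives) / k) / (n_actives / n_total)


def normalized_ef(labels: Sequence, scores: Sequence, alpha: float = 0.01,
                  ids: Sequence | None = None) -> float:
    """EF divided by the best achievable EF; lies in [0, 1]."""
    labels_arr = as_binary_labels(labels)
    ef = enrichment_factor(labels_arr, scores, alpha, ids)
    max_ef = max_enrichment_factor(int(labels_arr.sum()), labels_arr.size, alpha)
    return ef / max_ef


_METRIC_FUNCS: dict[str, Callable] = {
    "auc": lambda y, s, a: roc_auc(y, s),
    "ef": enrichment_factor,
    "nef": normalized_ef,
}


def _metric_callable(metric: str | Callable, alpha: float) -> Callable[[np.ndarray, np.ndarray], float]:
    if callable(metric):
        return metric
    if metric not in _METRIC_FUNCS:
        raise DomainError(f"unknown metric {metric!r}; expected one of {sorted(_METRIC_FUNCS)}")
    fn = _METRIC_FUNCS[metric]
    return lambda y, s: fn(y, s, alpha)


def bootstrap_interval(
    labels: Sequence,
    scores: Sequence,
    metric: str | Callable = "auc",
    alpha: float = 0.01,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for a screening metric.

    Actives and inactives are resampled with replacement *separately*, so each
    resample keeps the original class counts and every metric stays defined.

    Parameters
    ----------
    metric:
        ``"auc"``, ``"ef"``, ``"nef"`` or a callable ``f(labels, scores)``.
    alpha:
        Top fraction for ef/nef (ignored for auc and callables).
    level:
        Interval coverage level in (0, 1); the percentile method is used.
    """
    if n_boot < 100:
        raise DomainError(f"n_boot must be >= 100, got {n_boot}")
    if not 0 < level < 1:
        raise DomainError(f"level must be in (0, 1), got {level}")
    labels = as_binary_labels(labels)
    scores = np.asarray(scores, dtype=float)
    _validate_two_class(labels, scores)
    fn = _metric_callable(metric, alpha)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    act_scores = scores[labels == 1]
    inact_scores = scores[labels == 0]
    n_a, n_i = act_scores.size, inact_scores.size
    boot_labels = np.concatenate([np.ones(n_a, dtype=int), np.zeros(n_i, dtype=int)])
    stats_out = np.empty(n_boot)
    for b in range(n_boot):
        sa = act_scores[rng.integers(0, n_a, n_a)]
        si = inact_scores[rng.integers(0, n_i, n_i)]
        stats_out[b] = fn(boot_labels, np.concatenate([sa, si]))
    lo, hi = np.percentile(stats_out, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


def compare_distributions(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method_a: str = "a",
    method_b: str = "b",
    metric: str = "metric",
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test on two unpaired per-target metric vectors.

    Uses exact enumeration when both samples have n <= 8 and no ties; the
    normal approximation with tie correction otherwise.  Fully tied data give
    p = 1 (maximally unextreme).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("compare_distributions requires non-empty vectors")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        p = 1.0
    else:
        tie_free = np.unique(pooled).size == pooled.size
        mw_method = "exact" if (a.size <= 8 and b.size <= 8 and tie_free) else "asymptotic"
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=mw_method).pvalue)
    return ComparisonResult(method_a, method_b, metric, min(p, 1.0), int(a.size + b.size))


def summarize_benchmark(
    results: Iterable[MetricResult],
    statistic: str = "median",
    benchmark_of: Mapping[str, str] | None = None,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Summary table: one row per (benchmark, method, metric) with the median
    (or mean) over targets, a flag for the best method per column, and the
    Mann-Whitney p-value of each method's per-target distribution against the
    best method's (``indistinguishable`` = p > ``p_threshold``).

    ``benchmark_of`` maps target_id -> benchmark name; absent, all targets are
    pooled under one benchmark named "all".
    """
    if statistic not in ("median", "mean"):
        raise DomainError(f"statistic must be median or mean, got {statistic!r}")
    rows = [{
        "target": r.target_id, "method": r.method, "metric": r.metric,
        "alpha": np.nan if r.alpha is None else r.alpha, "value": r.value,
    } for r in results]
    if not rows:
        raise DomainError("no results to summarize")
    df = pd.DataFrame(rows)
    df["benchmark"] = (df["target"].map(benchmark_of) if benchmark_of is not None else "all")

    out_rows = []
    group_cols = ["benchmark", "metric", "alpha"]
    for (bench, metric, alpha), col in df.groupby(group_cols, sort=True, dropna=False):
        per_method = {m: g["value"].to_numpy() for m, g in col.groupby("method", sort=True)}
        stat = {m: (np.median(v) if statistic == "median" else np.mean(v))
                for m, v in per_method.items()}
        best = max(sorted(stat), key=lambda m: stat[m])
        for m in sorted(per_method):
            if m == best:
                p = 1.0
            else:
                p = compare_distributions(per_method[m], per_method[best], m, best, metric).p_value
            out_rows.append({
                "benchmark": bench, "method": m, "metric": metric, "alpha": alpha,
                statistic: float(stat[m]), "n_targets": int(per_method[m].size),
                "is_best": m == best, "p_vs_best": p,
                "indistinguishable_from_best": bool(p > p_threshold),
            })
    return pd.DataFrame(out_rows)


def significant_win_count(
    per_target: Mapping[str, tuple[Sequence, Sequence, Sequence]],
    metric: str | Callable = "nef",
    alpha: float = 0.01,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[int, int, int]:
    """Count targets where method A (or B) is significantly better.

    ``per_target`` maps target_id to ``(labels, scores_a, scores_b)`` — the
    same compounds scored by two methods.  For each target, compounds are
    resampled once per bootstrap iteration (stratified by class) and the
    metric difference A - B is evaluated on the shared resample; a target is a
    win for A when the percentile CI of the difference excludes 0 in A's
    favor, symmetrically for B, else undecided.

    Returns ``(wins_a, wins_b, undecided)``; the three always sum to the
    number of targets.
    """
    if n_boot < 100:
        raise DomainError(f"n_boot must be >= 100, got {n_boot}")
    fn = _metric_callable(metric, alpha)
    rng = np.random.default_rng(seed)
    wins_a = wins_b = undecided = 0
    q_lo, q_hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    for tid in sorted(per_target):
        labels, sa, sb = per_target[tid]
        labels = as_binary_labels(labels)
        sa = np.asarray(sa, dtype=float)
        sb = np.asarray(sb, dtype=float)
        if not (labels.size == sa.size == sb.size):
            raise IntegrityError(f"target {tid!r}: mismatched label/score lengths")
        _validate_two_class(labels, sa)
        idx_a = np.flatnonzero(labels == 1)
        idx_i = np.flatnonzero(labels == 0)
        boot_labels = np.concatenate([np.ones(idx_a.size, dtype=int),
                                      np.zeros(idx_i.size, dtype=int)])
        diffs = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate([idx_a[rng.integers(0, idx_a.size, idx_a.size)],
                                   idx_i[rng.integers(0, idx_i.size, idx_i.size)]])
            diffs[b] = fn(boot_labels, sa[take]) - fn(boot_labels, sb[take])
        lo, hi = np.percentile(diffs, [q_lo, q_hi])
        if lo > 0:
            wins_a += 1
        elif hi < 0:
            wins_b += 1
        else:
            undecided += 1
    return wins_a, wins_b, undecided
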