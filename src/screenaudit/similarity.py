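"""Training-set similarity analysis.

ML scoring functions can inherit performance from chemical overlap between a
benchmark's actives and their training pool.  The statistic used here: for
each benchmark active, take the maximum ECFP4 Tanimoto similarity to any
training-pool compound, then average those maxima per target.  Correlating
this per-target similarity with per-target early enrichment (Spearman rank
correlation, midranks for ties, two-sided p) quantifies how much screening
performance tracks training-set proximity.  Only actives enter the statistic
because affinity training pools contain no inactives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

__all__ = [
    "Fingerprint", "tanimoto", "tanimoto_matrix", "avg_max_similarity",
    "similarity_performance_correlation", "fp_to_hex", "hex_to_fp",
    "write_fingerprints", "read_fingerprints",
]


@dataclass
class Fingerprint:
    """A fixed-length binary fingerprint."""

    bits: np.ndarray
    scheme: str = "ecfp4"

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 1:
            raise DomainError("fingerprint bits must be a 1-D vector")

    @property
    def n_bits(self) -> int:
        return int(self.bits.size)


def _as_bits(fp) -> np.ndarray:
    if isinstance(fp, Fingerprint):
        return fp.bits
    return np.asarray(fp, dtype=bool)


def tanimoto(a, b) -> float:
    """|a AND b| / |a OR b|; two empty fingerprints have similarity 0 (not 0/0)."""
    a, b = _as_bits(a), _as_bits(b)
    if a.size != b.size:
        raise DomainError(f"fingerprint lengths differ: {a.size} vs {b.size}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def _as_matrix(fps) -> np.ndarray:
    if isinstance(fps, np.ndarray) and fps.ndim == 2:
        return fps.astype(bool)
    rows = [_as_bits(f) for f in fps]
    if not rows:
        raise DomainError("empty fingerprint collection")
    return np.vstack(rows)


def tanimoto_matrix(fps_a, fps_b) -> np.ndarray:
    """Pairwise Tanimoto similarities, shape (len(a), len(b))."""
    a = _as_matrix(fps_a)
    b = _as_matrix(fps_b)
    if a.shape[1] != b.shape[1]:
        raise DomainError(f"fingerprint lengths differ: {a.shape[1]} vs {b.shape[1]}")
    ai = a.sum(axis=1, dtype=np.int64)[:, None]
    bi = b.sum(axis=1, dtype=np.int64)[None, :]
    inter = a.astype(np.int64) @ b.astype(np.int64).T
    union = ai + bi - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim


def avg_max_similarity(target_actives, training_pool) -> float:
    """Mean over actives of the max Tanimoto similarity to any pool compound.

    Monotone non-decreasing as compounds are added to the pool; 1.0 when every
    active appears verbatim in the pool.
    """
    sim = tanimoto_matrix(target_actives, training_pool)
    if sim.size == 0:
        raise DomainError("avg_max_similarity requires non-empty inputs")
    return float(sim.max(axis=1).mean())


def similarity_performance_correlation(
    per_target_similarity: Sequence[float],
    per_target_metric: Sequence[float],
) -> tuple[float, float]:
    """Spearman rank correlation (midranks) between per-target training
    similarity and per-target screening performance; returns (rho, two-sided p).
    """
    x = np.asarray(per_target_similarity, dtype=float)
    y = np.asarray(per_target_metric, dtype=float)
    if x.size != y.size:
        raise DomainError("similarity and metric vectors must pair by target")
    if x.size < 3:
        raise DomainError(f"need at least 3 targets, got {x.size}")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DomainError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# --- fingerprint CSV round-trip (compound_id + hex-encoded bitstring) -------

def fp_to_hex(bits) -> str:
    bits = _as_bits(bits)
    return np.packbits(bits.astype(np.uint8)).tobytes().hex()


def hex_to_fp(hexstr: str, n_bits: int) -> np.ndarray:
    raw = np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8)
    return np.unpackbits(raw)[:n_bits].astype(bool)


def write_fingerprints(fps: dict[str, np.ndarray], path, n_bits: int | None = None) -> None:
    """Write fingerprints as CSV of (compound, n_bits, hex)."""
    rows = []
    for name, bits in fps.items():
        bits = _as_bits(bits)
        rows.append({"compound": name, "n_bits": int(bits.size), "fp_hex": fp_to_hex(bits)})
    pd.DataFrame(rows, columns=["compound", "n_bits", "fp_hex"]).to_csv(path, index=False)


def read_fingerprints(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, dtype={"fp_hex": str})
    return {str(r.compound): hex_to_fp(r.fp_hex, int(r.n_bits))
            for r in df.itertuples(index=False)}
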