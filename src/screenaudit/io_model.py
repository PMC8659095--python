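"""Canonical data model for scored screening benchmarks and on-disk readers/writers.

A screening benchmark is a set of *targets*; for each target every compound in
the library was docked against one or more receptor structures, producing a
ranked list of poses, each carrying one or more score channels (docking energy,
CNN pose probability, predicted affinity in pK units, ...) and optionally an
RMSD to a reference pose.

Score direction is canonicalized at ingest: channels declared ``lower_better``
(e.g. Vina/Vinardo energies) are negated when loaded, so every value stored in
a :class:`ScreenTable` is on a higher-is-better scale and all downstream
ranking code assumes descending-score order.  Negation is involutive, so the
original values are recoverable by negating again.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import InputError, IntegrityError, ParseError, SchemaError
from .metrics import MetricResult

logger = logging.getLogger(__name__)

#: columns with reserved meaning in a score table; everything else is a channel
RESERVED_COLUMNS = ("target", "compound", "label", "receptor", "pose_rank", "rmsd")

_LABEL_MAP = {
    "1": "active", "0": "inactive",
    "active": "active", "inactive": "inactive",
    "true": "active", "false": "inactive",
}


@dataclass(frozen=True)
class ScoreChannel:
    """One score column: its name, ranking direction, and semantic kind.

    ``kind`` is informational except for ``pose_prob``, whose values must lie
    in [0, 1] (they are probabilities that a pose is a binding mode).
    """

    name: str
    direction: str = "higher_better"  # or "lower_better"
    kind: str = "generic"  # pose_prob | affinity_pK | energy | generic

    def __post_init__(self) -> None:
        if self.direction not in ("higher_better", "lower_better"):
            raise SchemaError(f"unknown direction {self.direction!r} for channel {self.name!r}")
        if self.kind not in ("pose_prob", "affinity_pK", "energy", "generic"):
            raise SchemaError(f"unknown kind {self.kind!r} for channel {self.name!r}")


@dataclass
class PoseRecord:
    """One scored pose of one compound against one receptor."""

    target_id: str
    compound_id: str
    receptor_id: str
    pose_rank: int
    scores: dict[str, float]
    rmsd: float | None = None

    def __post_init__(self) -> None:
        if self.pose_rank < 1:
            raise IntegrityError(f"pose_rank must be >= 1, got {self.pose_rank}")
        if self.rmsd is not None and self.rmsd < 0:
            raise IntegrityError(f"rmsd must be non-negative, got {self.rmsd}")


class ScreenTable:
    """All scored poses for one benchmark target, with binary activity labels.

    Parameters
    ----------
    target_id:
        Benchmark target identifier.
    poses:
        DataFrame with columns ``compound``, ``receptor``, ``pose_rank``,
        optionally ``rmsd``, plus one numeric column per score channel.
        Values are assumed already canonical (higher is better).
    labels:
        Mapping ``compound_id -> "active" | "inactive"`` covering every
        compound in ``poses``.
    channels:
        The registered :class:`ScoreChannel` objects.
    """

    def __init__(
        self,
        target_id: str,
        poses: pd.DataFrame,
        labels: Mapping[str, str],
        channels: Iterable[ScoreChannel],
    ) -> None:
        self.target_id = str(target_id)
        self.poses = poses.reset_index(drop=True)
        self.labels = dict(labels)
        self.channels = {c.name: c for c in channels}
        self._validate()

    def _validate(self) -> None:
        for col in ("compound", "receptor", "pose_rank"):
            if col not in self.poses.columns:
                raise SchemaError(f"pose table for {self.target_id!r} lacks column {col!r}")
        missing = set(self.poses["compound"]) - set(self.labels)
        if missing:
            raise IntegrityError(
                f"target {self.target_id!r}: {len(missing)} compounds without labels "
                f"(e.g. {sorted(missing)[:3]})"
            )
        bad = {v for v in self.labels.values()} - {"active", "inactive"}
        if bad:
            raise IntegrityError(f"target {self.target_id!r}: non-binary labels {sorted(bad)}")
        keys = self.poses[["compound", "receptor", "pose_rank"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise IntegrityError(
                f"target {self.target_id!r}: duplicate (compound, receptor, pose_rank) key "
                f"{tuple(dup)}"
            )
        for name, ch in self.channels.items():
            if name not in self.poses.columns:
                raise SchemaError(f"channel {name!r} missing from pose table of {self.target_id!r}")
            vals = self.poses[name].to_numpy()
            if not np.all(np.isfinite(vals)):
                raise IntegrityError(f"non-finite {name!r} scores in target {self.target_id!r}")
            if ch.kind == "pose_prob" and ((vals < 0) | (vals > 1)).any():
                raise IntegrityError(f"pose_prob channel {name!r} has values outside [0, 1]")
        if "rmsd" in self.poses.columns:
            r = self.poses["rmsd"].to_numpy(dtype=float)
            if np.nanmin(r, initial=0.0) < 0:
                raise IntegrityError(f"negative rmsd in target {self.target_id!r}")

    @property
    def compounds(self) -> list[str]:
        return list(dict.fromkeys(self.poses["compound"]))

    @property
    def n_actives(self) -> int:
        return sum(1 for v in self.labels.values() if v == "active")

    @property
    def n_inactives(self) -> int:
        return sum(1 for v in self.labels.values() if v == "inactive")

    def records(self) -> Iterator[PoseRecord]:
        """Iterate poses as :class:`PoseRecord` objects (convenience view)."""
        has_rmsd = "rmsd" in self.poses.columns
        for row in self.poses.itertuples(index=False):
            d = row._asdict()
            yield PoseRecord(
                target_id=self.target_id,
                compound_id=d["compound"],
                receptor_id=d["receptor"],
                pose_rank=int(d["pose_rank"]),
                scores={name: float(d[name]) for name in self.channels},
                rmsd=float(d["rmsd"]) if has_rmsd and pd.notna(d["rmsd"]) else None,
            )


@dataclass
class Benchmark:
    """A named collection of per-target screen tables."""

    name: str
    targets: dict[str, ScreenTable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, table in self.targets.items():
            if tid != table.target_id:
                raise IntegrityError(f"target key {tid!r} != table.target_id {table.target_id!r}")

    def __iter__(self) -> Iterator[ScreenTable]:
        return iter(self.targets.values())

    def __len__(self) -> int:
        return len(self.targets)


def normalize_label(raw: object) -> str:
    """Map a raw label (1/0, active/inactive, true/false; any case) to canonical form."""
    key = str(raw).strip().lower()
    if key not in _LABEL_MAP:
        raise ParseError(f"unrecognized activity label {raw!r}")
    return _LABEL_MAP[key]


def read_score_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    channels: Iterable[ScoreChannel] | None = None,
    name: str | None = None,
) -> Benchmark:
    """Read a delimited per-pose score table into a :class:`Benchmark`.

    The file must be comma- or tab-separated with a header.  Required logical
    columns are ``target``, ``compound``, ``label`` and at least one score
    channel; ``receptor`` (default: single receptor ``r0``), ``pose_rank``
    (default: file order within each (target, compound, receptor) group) and
    ``rmsd`` are optional.  ``schema`` maps logical names to the actual column
    names in the file.  ``channels`` declares direction/kind per score column;
    undeclared non-reserved columns become generic higher-is-better channels.

    Channels declared ``lower_better`` are negated on load (see module notes).
    """
    path = Path(path)
    sep = "\t" if "\t" in path.open("r", encoding="utf-8").readline() else ","
    df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    schema = dict(schema or {})
    rename = {schema.get(k, k): k for k in RESERVED_COLUMNS if schema.get(k, k) in df.columns}
    df = df.rename(columns=rename)

    for col in ("target", "compound", "label"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found in {path.name} "
                              f"(have: {list(df.columns)})")

    channel_list = list(channels) if channels is not None else [
        ScoreChannel(c) for c in df.columns if c not in RESERVED_COLUMNS
    ]
    if not channel_list:
        raise SchemaError(f"no score channel columns found in {path.name}")
    for ch in channel_list:
        mapped = schema.get(ch.name, ch.name)
        if mapped != ch.name and mapped in df.columns:
            df = df.rename(columns={mapped: ch.name})
        if ch.name not in df.columns:
            raise SchemaError(f"channel column {ch.name!r} not found in {path.name}")

    # numeric conversion with row-level diagnostics (header is line 1)
    numeric_cols = [c.name for c in channel_list] + (["rmsd"] if "rmsd" in df.columns else [])
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if col == "rmsd":
            bad &= df[col].str.strip().ne("")
        if bad.any():
            rows = [int(i) + 2 for i in df.index[bad][:5]]
            raise ParseError(f"non-numeric {col!r} value(s) at file row(s) {rows} of {path.name}")
        if col != "rmsd" and converted.isna().any():
            rows = [int(i) + 2 for i in df.index[converted.isna()][:5]]
            raise ParseError(f"missing {col!r} value(s) at file row(s) {rows} of {path.name}")
        df[col] = converted

    try:
        df["label"] = df["label"].map(normalize_label)
    except ParseError as exc:
        raise ParseError(f"{exc} in {path.name}") from None

    if "receptor" not in df.columns:
        df["receptor"] = "r0"
    if "pose_rank" in df.columns:
        df["pose_rank"] = pd.to_numeric(df["pose_rank"], errors="raise").astype(int)
    else:
        df["pose_rank"] = df.groupby(["target", "compound", "receptor"]).cumcount() + 1

    dup = df.duplicated(subset=["target", "compound", "receptor", "pose_rank"])
    if dup.any():
        key = tuple(df.loc[dup.idxmax(), ["target", "compound", "receptor", "pose_rank"]])
        raise IntegrityError(f"duplicate pose key {key} in {path.name}")

    # canonicalize: store every channel on a higher-is-better scale
    for ch in channel_list:
        if ch.direction == "lower_better":
            df[ch.name] = -df[ch.name]

    targets: dict[str, ScreenTable] = {}
    keep = ["compound", "receptor", "pose_rank"] + (
        ["rmsd"] if "rmsd" in df.columns else []) + [c.name for c in channel_list]
    for tid, sub in df.groupby("target", sort=True):
        labels = dict(zip(sub["compound"], sub["label"]))
        inconsistent = sub.groupby("compound")["label"].nunique()
        if (inconsistent > 1).any():
            raise IntegrityError(
                f"target {tid!r}: compound(s) with conflicting labels: "
                f"{list(inconsistent.index[inconsistent > 1])[:3]}"
            )
        targets[str(tid)] = ScreenTable(str(tid), sub[keep].copy(), labels, channel_list)

    logger.info("read %d targets, %d poses from %s", len(targets), len(df), path.name)
    return Benchmark(name=name or path.stem, targets=targets)


class MoleculeSet:
    """Named molecules parsed from a SMILES (or SDF) file, with a skip count."""

    def __init__(self, molecules: dict[str, object], n_skipped: int = 0) -> None:
        self.molecules = molecules
        self.n_skipped = n_skipped

    def __len__(self) -> int:
        return len(self.molecules)

    def __getitem__(self, name: str) -> object:
        return self.molecules[name]

    def items(self):
        return self.molecules.items()


def read_molecules(path: str | Path, fmt: str | None = None) -> MoleculeSet:
    """Read molecules from a SMILES file (``SMILES whitespace name`` per line).

    SDF input is supported as an adapter when ``fmt="sdf"`` or the file ends in
    ``.sdf``.  Unparsable records are skipped and counted; duplicate names are
    an integrity error; zero parsable records is an input error.
    """
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    path = Path(path)
    fmt = fmt or ("sdf" if path.suffix.lower() == ".sdf" else "smi")
    mols: dict[str, object] = {}
    n_skipped = 0

    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                n_skipped += 1
                continue
            nm = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i + 1}"
            if nm in mols:
                raise IntegrityError(f"duplicate molecule name {nm!r} in {path.name}")
            mols[nm] = mol
    else:
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                mol = Chem.MolFromSmiles(parts[0])
                if mol is None or len(parts) < 2:
                    n_skipped += 1
                    continue
                nm = parts[1].strip()
                if nm in mols:
                    raise IntegrityError(f"duplicate molecule name {nm!r} at line {lineno} of {path.name}")
                mols[nm] = mol

    if not mols:
        raise InputError(f"no parsable molecule records in {path.name}")
    if n_skipped:
        logger.warning("skipped %d unparsable records in %s", n_skipped, path.name)
    return MoleculeSet(mols, n_skipped)


_RESULT_COLUMNS = ["target", "method", "channel", "metric", "alpha",
                   "value", "ci_low", "ci_high", "n_boot"]


def write_results(results: Iterable[MetricResult], path: str | Path) -> None:
    """Write metric results to CSV; round-trips exactly through :func:`read_results`."""
    rows = []
    for r in results:
        rows.append({
            "target": r.target_id, "method": r.method, "channel": r.channel,
            "metric": r.metric, "alpha": r.alpha, "value": r.value,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "n_boot": r.n_boot,
        })
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> list[MetricResult]:
    """Read a CSV written by :func:`write_results` back into MetricResult objects."""
    df = pd.read_csv(path)
    missing = set(_RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"results file lacks columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(MetricResult(
            target_id=str(row.target), method=str(row.method),
            channel=None if pd.isna(row.channel) else str(row.channel),
            metric=str(row.metric),
            alpha=None if pd.isna(row.alpha) else float(row.alpha),
            value=float(row.value),
            ci_low=None if pd.isna(row.ci_low) else float(row.ci_low),
            ci_high=None if pd.isna(row.ci_high) else float(row.ci_high),
            n_boot=None if pd.isna(row.n_boot) else int(row.n_boot),
        ))
    return out
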