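"""Ligand-only descriptor baselines.

Decoy-set benchmarks can leak activity labels through trivially computable
ligand properties (the very descriptors used to select decoys).  To audit for
this, simple regression models are fit to *affinity* training data using only
cheap 2D descriptors, then used to rank a screening benchmark: any early
enrichment they achieve is attainable without ever looking at the protein, and
caps how much of a structure-based method's performance can be credited to
protein-ligand modelling.

Three descriptor sets are supported:

* ``dude6`` — molecular weight, H-bond acceptors, H-bond donors, rotatable
  bonds, logP, net formal charge (the property-matching features of
  decoy-selection pipelines).
* ``muv17`` — Lipinski HBA/HBD, logP, all-atom and heavy-atom counts, counts
  of B/Br/C/Cl/F/I/N/O/P/S atoms, potential stereocenters (assigned or not),
  and ring systems (fused rings count once).
* ``ecfp4`` — circular fingerprint of diameter 4 (Morgan radius 2), folded to
  a configurable bit length (default 2048).

Conventions: HBA counts N/O acceptors and HBD counts N-H/O-H donors
(Lipinski-style); logP is the Crippen atomic-contribution estimate; net charge
is the formal charge sum.  These follow common decoy-construction practice —
the feature names alone do not pin the conventions down.

Model fitting is sklearn grid-search cross-validation over small shipped grids
(six families: Lasso, KNN, decision tree, random forest, gradient boosting,
SVR), refit on all data at the best grid point.  The statistical core only
ever sees numeric tables, so precomputed descriptor CSVs can substitute for a
chemistry toolkit entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DomainError, IntegrityError

logger = logging.getLogger(__name__)

__all__ = [
    "DESCRIPTOR_SETS", "BaselineModelSpec", "compute_descriptors",
    "fingerprint_array", "fit_baseline", "screen_with_baseline",
    "best_baseline_per_target", "default_grids",
]

DUDE6_FEATURES = ["mol_weight", "hba", "hbd", "rotatable_bonds", "logp", "net_charge"]
MUV17_FEATURES = [
    "hba", "hbd", "logp", "n_atoms_all", "n_atoms_heavy",
    "n_boron", "n_bromine", "n_carbon", "n_chlorine", "n_fluorine", "n_iodine",
    "n_nitrogen", "n_oxygen", "n_phosphorus", "n_sulfur",
    "n_chiral_centers", "n_ring_systems",
]
DESCRIPTOR_SETS = {"dude6": DUDE6_FEATURES, "muv17": MUV17_FEATURES, "ecfp4": None}


def _ring_system_count(mol) -> int:
    """Connected components of the ring-bond subgraph (fused systems count once)."""
    ri = mol.GetRingInfo()
    atom_rings = [set(r) for r in ri.AtomRings()]
    merged: list[set] = []
    for ring in atom_rings:
        overlapping = [m for m in merged if m & ring]
        for m in overlapping:
            merged.remove(m)
            ring = ring | m
        merged.append(ring)
    return len(merged)


def _element_count(mol, symbol: str) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() == symbol)


def _dude6_row(mol) -> dict[str, float]:
    from rdkit.Chem import Crippen, Descriptors, Lipinski, rdmolops

    return {
        "mol_weight": Descriptors.MolWt(mol),
        "hba": Lipinski.NumHAcceptors(mol),
        "hbd": Lipinski.NumHDonors(mol),
        "rotatable_bonds": Lipinski.NumRotatableBonds(mol),
        "logp": Crippen.MolLogP(mol),
        "net_charge": rdmolops.GetFormalCharge(mol),
    }


def _muv17_row(mol) -> dict[str, float]:
    from rdkit import Chem
    from rdkit.Chem import Crippen, Lipinski

    mol_h = Chem.AddHs(mol)
    chiral = Chem.FindMolChiralCenters(mol, includeUnassigned=True,
                                       useLegacyImplementation=False)
    return {
        "hba": Lipinski.NumHAcceptors(mol),
        "hbd": Lipinski.NumHDonors(mol),
        "logp": Crippen.MolLogP(mol),
        "n_atoms_all": mol_h.GetNumAtoms(),
        "n_atoms_heavy": mol.GetNumHeavyAtoms(),
        "n_boron": _element_count(mol, "B"),
        "n_bromine": _element_count(mol, "Br"),
        "n_carbon": _element_count(mol, "C"),
        "n_chlorine": _element_count(mol, "Cl"),
        "n_fluorine": _element_count(mol, "F"),
        "n_iodine": _element_count(mol, "I"),
        "n_nitrogen": _element_count(mol, "N"),
        "n_oxygen": _element_count(mol, "O"),
        "n_phosphorus": _element_count(mol, "P"),
        "n_sulfur": _element_count(mol, "S"),
        "n_chiral_centers": len(chiral),
        "n_ring_systems": _ring_system_count(mol),
    }


def fingerprint_array(mol, n_bits: int = 2048) -> np.ndarray:
    """ECFP4 (Morgan radius-2) fingerprint folded to ``n_bits``, as a 0/1 array."""
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def compute_descriptors(
    molecules: Mapping[str, object],
    set_name: str,
    n_bits: int = 2048,
) -> pd.DataFrame:
    """Compute a descriptor table (rows = compounds) for one descriptor set.

    Molecules on which a descriptor computation fails are excluded with a
    logged warning; results are deterministic per molecule and invariant to
    SMILES atom ordering.
    """
    if set_name not in DESCRIPTOR_SETS:
        raise DomainError(f"unknown descriptor set {set_name!r}; expected {sorted(DESCRIPTOR_SETS)}")
    rows: dict[str, object] = {}
    for name, mol in molecules.items():
        try:
            if set_name == "dude6":
                rows[name] = _dude6_row(mol)
            elif set_name == "muv17":
                rows[name] = _muv17_row(mol)
            else:
                rows[name] = dict(enumerate(fingerprint_array(mol, n_bits)))
        except Exception as exc:  # descriptor failure on one molecule
            logger.warning("descriptor failure on %s: %s; excluded", name, exc)
    if not rows:
        raise DomainError("no molecules yielded descriptors")
    if set_name == "ecfp4":
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.columns = [f"bit{int(c)}" for c in df.columns]
    else:
        df = pd.DataFrame.from_dict(rows, orient="index")[DESCRIPTOR_SETS[set_name]]
    df.index.name = "compound"
    return df.astype(float)


def default_grids() -> dict:
    """The shipped hyperparameter grids, keyed by model family."""
    text = resources.files("screenaudit.data").joinpath("baseline_grids.yaml").read_text()
    return yaml.safe_load(text)


FAMILIES = ("lasso", "knn", "decision_tree", "random_forest", "gradient_boosting", "svr")


@dataclass
class BaselineModelSpec:
    """One baseline family with its search grid and CV settings."""

    family: str
    grid: dict | None = None  # None -> shipped default grid
    cv_folds: int = 5
    seed: int = 0
    scale: bool | None = None  # None -> family default

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}; expected {FAMILIES}")
        if self.cv_folds < 2:
            raise ConfigError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.grid is not None and not self.grid:
            raise ConfigError("hyperparameter grid must be non-empty")


def _make_estimator(family: str, seed: int):
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.linear_model import Lasso
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.svm import SVR
    from sklearn.tree import DecisionTreeRegressor

    return {
        "lasso": lambda: Lasso(max_iter=50_000, random_state=seed),
        "knn": KNeighborsRegressor,
        "decision_tree": lambda: DecisionTreeRegressor(random_state=seed),
        "random_forest": lambda: RandomForestRegressor(random_state=seed, n_jobs=1),
        "gradient_boosting": lambda: GradientBoostingRegressor(random_state=seed),
        "svr": SVR,
    }[family]()


def fit_baseline(
    train: pd.DataFrame,
    affinities: Mapping[str, float] | pd.Series,
    spec: BaselineModelSpec,
):
    """Grid-search CV fit of one baseline family to affinity (pK) data.

    ``train`` is a compound-indexed descriptor table; ``affinities`` maps
    compound to pK.  Returns the model refit on all data at the grid point
    with the best cross-validated squared error; deterministic under the
    spec's seed.
    """
    from sklearn.model_selection import GridSearchCV, KFold
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    y = pd.Series(dict(affinities) if not isinstance(affinities, pd.Series) else affinities)
    y = y.reindex(train.index)
    if y.isna().any() or not np.isfinite(y.to_numpy()).all():
        raise IntegrityError("non-finite or missing affinity for some training compounds")
    if len(train) < spec.cv_folds * 5:
        raise DomainError(
            f"need at least {spec.cv_folds * 5} training compounds for {spec.cv_folds}-fold CV, "
            f"got {len(train)}")

    cfg = default_grids()[spec.family]
    grid = spec.grid if spec.grid is not None else cfg["grid"]
    scale = spec.scale if spec.scale is not None else bool(cfg["scale"])
    # yaml null -> None already handled by safe_load
    steps = ([("scale", StandardScaler())] if scale else []) + [
        ("model", _make_estimator(spec.family, spec.seed))]
    cv = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(Pipeline(steps), grid, cv=cv,
                          scoring="neg_mean_squared_error", refit=True, n_jobs=1)
    search.fit(train.to_numpy(), y.to_numpy())
    search.feature_names_ = list(train.columns)
    return search


def screen_with_baseline(model, bench: pd.DataFrame) -> pd.Series:
    """Rank a benchmark by predicted affinity (higher = better).

    ``bench`` must have the same feature width (and names, when known) as the
    training table the model was fit on.
    """
    names = getattr(model, "feature_names_", None)
    if names is not None:
        if set(names) != set(bench.columns):
            raise IntegrityError(
                f"benchmark features do not match training features "
                f"({len(bench.columns)} vs {len(names)} columns)")
        bench = bench[names]
    preds = model.predict(bench.to_numpy())
    return pd.Series(preds, index=bench.index, name="score")


def best_baseline_per_target(
    results: pd.DataFrame,
    metric: str = "nef",
) -> pd.DataFrame:
    """Per-target maximum over all baseline configurations.

    ``results`` needs columns ``target``, ``config`` (family/descriptor-set/
    training-set identity) , ``metric`` and ``value``.  Returns one row per
    target with the max value and the configuration that achieves it (ties
    broken by lexicographic config id).
    """
    for col in ("target", "config", "metric", "value"):
        if col not in results.columns:
            raise IntegrityError(f"results table lacks column {col!r}")
    sub = results[results["metric"] == metric]
    if sub.empty:
        raise DomainError(f"no rows with metric {metric!r}")
    sub = sub.sort_values(["target", "value", "config"],
                          ascending=[True, False, True], kind="mergesort")
    best = sub.groupby("target", sort=True).first().reset_index()
    return best[["target", "config", "value"]].rename(columns={"value": f"best_{metric}"})
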