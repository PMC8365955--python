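"""Reading, standardizing, de-conflicting and splitting labeled SMILES sets.

The training protocol is *step-wise*: base neural models and the stacking
(meta) model must never see each other's training labels, so a dataset is cut
into four disjoint roles — base-train, base-valid, meta-train, meta-valid —
either once (a fractional split) or rotated under consecutive-splitting
k-fold cross-validation.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord",
    "LabeledDataset",
    "StepwiseSplit",
    "CVFoldPlan",
    "SmilesParseError",
    "ConfigurationError",
    "read_dataset_csv",
    "standardize_molecule",
    "reconcile_labels",
    "stepwise_split",
    "consecutive_cv_folds",
    "write_dataset_csv",
    "write_split_manifest",
]

ROLE_NAMES = ("base_train", "base_valid", "meta_train", "meta_valid")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class ConfigurationError(ValueError):
    """Raised for invalid user configuration (columns, fractions, fold counts)."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: canonical SMILES, binary hERG label, provenance tag."""

    smiles: str
    label: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class LabeledDataset:
    """Ordered collection of labeled molecules."""

    records: list[MoleculeRecord]
    name: str = "dataset"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def subset(self, indices: Sequence[int], name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(
            [self.records[i] for i in indices], name or self.name
        )


@dataclass
class StepwiseSplit:
    """Four disjoint partitions for step-wise training, plus the seed used."""

    base_train: LabeledDataset
    base_valid: LabeledDataset
    meta_train: LabeledDataset
    meta_valid: LabeledDataset
    seed: int

    def roles(self) -> dict[str, LabeledDataset]:
        return {r: getattr(self, r) for r in ROLE_NAMES}


@dataclass
class CVFoldPlan:
    """Rotation of k consecutive parts over the four step-wise roles.

    Fold i uses part i as base-valid, part i+1 (mod k) as meta-train,
    part i+2 (mod k) as meta-valid and the remaining k-3 parts as base-train.
    """

    k: int
    parts: list[list[int]] = field(repr=False)  # index lists, one per part

    def fold_roles(self, fold: int) -> dict[str, list[int]]:
        """Index lists per role for one fold."""
        if not 0 <= fold < self.k:
            raise ValueError(f"fold must be in [0, {self.k})")
        bv, mt, mv = fold, (fold + 1) % self.k, (fold + 2) % self.k
        base_train: list[int] = []
        for p in range(self.k):
            if p not in (bv, mt, mv):
                base_train.extend(self.parts[p])
        return {
            "base_train": base_train,
            "base_valid": list(self.parts[bv]),
            "meta_train": list(self.parts[mt]),
            "meta_valid": list(self.parts[mv]),
        }

    def fold_split(self, dataset: LabeledDataset, fold: int, seed: int = 0) -> StepwiseSplit:
        roles = self.fold_roles(fold)
        return StepwiseSplit(
            *(dataset.subset(roles[r], f"{dataset.name}:{r}[fold{fold}]") for r in ROLE_NAMES),
            seed=seed,
        )


# ---------------------------------------------------------------------------
# standardization


def _standardizer_pipeline():
    # constructed lazily per call; RDKit standardizer objects are cheap
    return rdMolStandardize.LargestFragmentChooser(), rdMolStandardize.Uncharger()


def standardize_molecule(smiles: str) -> str:
    """Standardize a SMILES string to a canonical form.

    Pipeline: parse, keep the largest fragment (salt stripping), neutralize
    formal charges, then emit RDKit canonical SMILES. Idempotent: running the
    output through again returns the same string.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    chooser, uncharger = _standardizer_pipeline()
    mol = chooser.choose(mol)
    mol = uncharger.uncharge(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# I/O


def read_dataset_csv(
    path: str | Path,
    smiles_column: str = "smiles",
    label_column: str = "label",
    name: str | None = None,
    standardize: bool = True,
) -> LabeledDataset:
    """Load a (smiles, label) CSV into a LabeledDataset.

    Rows whose SMILES fail to parse are skipped and counted in the log rather
    than aborting the load. Labels must be 0/1 (integers or numeric strings).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ConfigurationError(f"empty file: {path}")
        for col in (smiles_column, label_column):
            if col not in reader.fieldnames:
                raise ConfigurationError(
                    f"column {col!r} not in {reader.fieldnames} of {path}"
                )
        records: list[MoleculeRecord] = []
        skipped = 0
        for row in reader:
            raw = row[smiles_column].strip()
            try:
                smi = standardize_molecule(raw) if standardize else raw
            except SmilesParseError:
                skipped += 1
                continue
            records.append(
                MoleculeRecord(smi, int(float(row[label_column])), str(path))
            )
    if skipped:
        logger.warning("%s: skipped %d unparseable SMILES rows", path, skipped)
    if not records:
        raise ConfigurationError(f"no usable rows in {path}")
    return LabeledDataset(records, name or path.stem)


def write_dataset_csv(dataset: LabeledDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["smiles", "label"])
        for r in dataset:
            w.writerow([r.smiles, r.label])


def write_split_manifest(split: StepwiseSplit, path: str | Path) -> None:
    """Persist a split as CSV with a ``role`` column."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["smiles", "label", "role"])
        for role, ds in split.roles().items():
            for r in ds:
                w.writerow([r.smiles, r.label, role])


# ---------------------------------------------------------------------------
# reconciliation and splitting


def reconcile_labels(dataset: LabeledDataset) -> LabeledDataset:
    """Collapse duplicate SMILES; drop SMILES observed with both labels.

    Duplicates with a consistent label keep their first occurrence.
    Inconsistently labeled structures carry no usable signal and are removed
    entirely; the removal count is logged.
    """
    labels_seen: dict[str, set[int]] = {}
    first: dict[str, MoleculeRecord] = {}
    for rec in dataset:
        labels_seen.setdefault(rec.smiles, set()).add(rec.label)
        first.setdefault(rec.smiles, rec)
    conflicted = {s for s, ls in labels_seen.items() if len(ls) > 1}
    if conflicted:
        logger.info(
            "%s: removed %d inconsistently labeled structures",
            dataset.name,
            len(conflicted),
        )
    kept = [
        rec
        for smi, rec in first.items()
        if smi not in conflicted
    ]
    return LabeledDataset(kept, dataset.name)


def stepwise_split(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float, float] = (0.7, 0.1, 0.1, 0.1),
    seed: int = 42,
) -> StepwiseSplit:
    """Seeded shuffle, then contiguous cuts at the cumulative fractions."""
    if len(fractions) != 4:
        raise ConfigurationError("exactly four fractions required")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1, got {sum(fractions)}")
    if len(dataset) == 0:
        raise ConfigurationError("cannot split an empty dataset")
    n = len(dataset)
    order = np.random.default_rng(seed).permutation(n)
    bounds = np.cumsum([round(f * n) for f in fractions[:3]])
    chunks = np.split(order, bounds)
    parts = [
        dataset.subset(chunk.tolist(), f"{dataset.name}:{role}")
        for chunk, role in zip(chunks, ROLE_NAMES)
    ]
    return StepwiseSplit(*parts, seed=seed)


def consecutive_cv_folds(dataset: LabeledDataset, k: int = 10) -> CVFoldPlan:
    """Cut the dataset into k consecutive parts for rotating-role CV."""
    if k < 4:
        raise ConfigurationError("k must be >= 4: four roles must be fillable")
    if len(dataset) < k:
        raise ConfigurationError(f"dataset of {len(dataset)} too small for k={k}")
    idx = np.arange(len(dataset))
    parts = [p.tolist() for p in np.array_split(idx, k)]
    return CVFoldPlan(k=k, parts=parts)
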