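"""Synthetic labeled SMILES datasets with a planted structure-activity rule.

Molecules are assembled from a small grammar — a random ring/chain scaffold
decorated with random substituents — and a pharmacophore-like motif
(4-phenyl-1-methylpiperazine: an aromatic ring joined to a basic amine) is
attached to exactly the molecules drawn as positives. The label is therefore
a deterministic function of structure, optionally corrupted by independent
label flips, which makes the rule recoverable by every feature view:
descriptors (amine/aromatic counts), graphs, fingerprints and token
sequences all change when the motif is present.

The motif is attached last and its interior atoms are never decorated, so
its interior Morgan environments are identical across molecules and the rule
is visible even to single fingerprint bits.

This generator emulates the *shape* of curated hERG datasets (SMILES +
binary label, tunable class balance and label noise) — not hERG
pharmacology or the descriptor distributions of real drug-like compounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .dataio import LabeledDataset, MoleculeRecord
from .featurize import MAX_ATOMS, MAX_TOKENS, tokenize_smiles

__all__ = ["SyntheticSpec", "GenerationError", "generate_synthetic_dataset", "MOTIF_SMILES"]

#: planted pharmacophore-like motif: aromatic ring + basic (piperazine) amine.
#: Atom 0 is the attachment point (a phenyl carbon).
MOTIF_SMILES = "c1ccc(cc1)N1CCN(C)CC1"

_SCAFFOLDS = (
    "c1ccccc1",      # benzene
    "c1ccncc1",      # pyridine
    "c1ccc2ccccc2c1",  # naphthalene
    "C1CCCCC1",      # cyclohexane
    "c1ccoc1",       # furan
    "c1ccsc1",       # thiophene
    "C1CCOCC1",      # tetrahydropyran
    "CCCCC",         # pentane chain
    "c1ccc(CCc2ccccc2)cc1",  # bibenzyl
)

# substituent fragments; attachment at atom index 0
_SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "O", "OC", "F", "Cl", "Br",
    "C(F)(F)F", "C#N", "C(=O)C", "C(=O)OC", "S(C)(=O)=O", "c1ccccc1",
)


class GenerationError(RuntimeError):
    """Raised when a valid molecule cannot be produced within bounded retries."""


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n: int = 2000
    positive_fraction: float = 0.53  # class balance of curated hERG sets
    noise_rate: float = 0.0         # independent label-flip probability
    motif: str = MOTIF_SMILES
    max_substituents: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        for name in ("positive_fraction", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


def _attach(mol: Chem.Mol, atom_idx: int, fragment: Chem.Mol,
            frag_attach: int = 0) -> Chem.Mol:
    combo = Chem.RWMol(Chem.CombineMols(mol, fragment))
    combo.AddBond(atom_idx, mol.GetNumAtoms() + frag_attach, Chem.BondType.SINGLE)
    out = combo.GetMol()
    Chem.SanitizeMol(out)
    return out


def _h_bearing_atoms(mol: Chem.Mol, limit: int | None = None) -> list[int]:
    """Indices of substitutable atoms; ``limit`` restricts to the first atoms
    (used to keep motif interiors undecorated)."""
    n = mol.GetNumAtoms() if limit is None else min(limit, mol.GetNumAtoms())
    return [
        i for i in range(n)
        if mol.GetAtomWithIdx(i).GetTotalNumHs() > 0
    ]


def _build_molecule(rng: np.random.Generator, spec: SyntheticSpec,
                    motif: Chem.Mol, positive: bool) -> str | None:
    mol = Chem.MolFromSmiles(_SCAFFOLDS[rng.integers(len(_SCAFFOLDS))])
    for _ in range(int(rng.integers(0, spec.max_substituents + 1))):
        sites = _h_bearing_atoms(mol)
        if not sites:
            break
        frag = Chem.MolFromSmiles(_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))])
        try:
            mol = _attach(mol, int(sites[rng.integers(len(sites))]), frag)
        except (Chem.AtomValenceException, Chem.KekulizeException):
            return None
    n_scaffold = mol.GetNumAtoms()
    if positive:
        sites = _h_bearing_atoms(mol, limit=n_scaffold)
        if not sites:
            return None
        try:
            mol = _attach(mol, int(sites[rng.integers(len(sites))]), motif)
        except (Chem.AtomValenceException, Chem.KekulizeException):
            return None
    smiles = Chem.MolToSmiles(mol)
    if mol.GetNumAtoms() > MAX_ATOMS or len(tokenize_smiles(smiles)) > MAX_TOKENS:
        return None
    # the planted rule must hold exactly: motif present iff positive
    if mol.HasSubstructMatch(motif) != positive:
        return None
    return smiles


def generate_synthetic_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Generate ``spec.n`` unique molecules labeled by the planted rule.

    Labels equal motif presence, then flip independently with probability
    ``spec.noise_rate``. Reproducible: the same spec (including seed) yields
    a byte-identical dataset.
    """
    rng = np.random.default_rng(spec.seed)
    motif = Chem.MolFromSmiles(spec.motif)
    if motif is None:
        raise ValueError(f"motif does not parse: {spec.motif!r}")
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    max_attempts = 200 * spec.n
    attempts = 0
    while len(records) < spec.n:
        if attempts >= max_attempts:
            raise GenerationError(
                f"could not generate {spec.n} unique molecules "
                f"in {max_attempts} attempts"
            )
        attempts += 1
        positive = bool(rng.random() < spec.positive_fraction)
        smiles = _build_molecule(rng, spec, motif, positive)
        if smiles is None or smiles in seen:
            continue
        seen.add(smiles)
        label = int(positive)
        if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
            label = 1 - label
        records.append(MoleculeRecord(smiles, label, source="synthetic"))
    return LabeledDataset(records, name=f"synthetic(seed={spec.seed})")
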