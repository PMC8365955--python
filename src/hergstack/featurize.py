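"""The five molecular representations feeding the base models.

Every featurizer is a pure, deterministic function of a canonical SMILES
string (plus fitted state for the normalizer and vocabulary):

* ``compute_descriptor_vector``  — physicochemical descriptors, min-max
  normalized to [0,1] with statistics learned on the base training set;
* ``featurize_graph``            — molecular graph as a zero-padded
  (max_atoms x 65) one-hot node matrix and (max_atoms x max_atoms) adjacency;
* ``compute_combined_fingerprints`` — 1024-bit ECFP2 (Morgan radius 1)
  concatenated with an 881-bit substructure-key block;
* ``encode_smiles_tokens``       — SMILES token ids, right-padded;
* ``compute_fp_index_vector``    — on-bit indices of a 1024-bit Morgan
  radius-2 fingerprint, 1-based, right-padded with the 0 sentinel.

The 881-bit block is a synthetic stand-in for the PubChem substructure keys:
RDKit's pattern (substructure-probe) fingerprint folded to 881 bits. It has
the same shape and 0/1 semantics; the specific key definitions differ.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, rdFingerprintGenerator

from .dataio import SmilesParseError

logger = logging.getLogger(__name__)

__all__ = [
    "DESCRIPTOR_NAMES",
    "N_DESCRIPTORS",
    "DescriptorNormalizer",
    "GraphFeatures",
    "TokenVocabulary",
    "OversizeMoleculeError",
    "OverlengthError",
    "compute_raw_descriptors",
    "compute_descriptor_vector",
    "fit_descriptor_normalizer",
    "featurize_graph",
    "compute_combined_fingerprints",
    "tokenize_smiles",
    "build_token_vocabulary",
    "encode_smiles_tokens",
    "compute_fp_index_vector",
    "BASE_FEATURE_NAMES",
]

#: canonical order of the five base representations
BASE_FEATURE_NAMES = ("DESC", "MGF", "MFP", "SeV", "FPeV")

# -- descriptors ------------------------------------------------------------

#: fixed 2D physicochemical descriptor list (RDKit's registry order)
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(n for n, _ in Descriptors._descList)
N_DESCRIPTORS = len(DESCRIPTOR_NAMES)

N_ECFP_BITS = 1024
N_KEY_BITS = 881
N_COMBINED_BITS = N_ECFP_BITS + N_KEY_BITS
MAX_ATOMS = 50
N_ATOM_FEATURES = 65
MAX_TOKENS = 97
MAX_FP_INDICES = 93

_ecfp2_gen = rdFingerprintGenerator.GetMorganGenerator(radius=1, fpSize=N_ECFP_BITS)
_morgan_r2_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=N_ECFP_BITS)


class OversizeMoleculeError(ValueError):
    """Molecule exceeds the maximum atom count of the graph featurizer."""


class OverlengthError(ValueError):
    """Token or index sequence exceeds its fixed maximum length."""


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def compute_raw_descriptors(smiles: str) -> np.ndarray:
    """Raw (unnormalized) descriptor vector; non-finite values become 0."""
    mol = _mol_from_smiles(smiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = Descriptors.CalcMolDescriptors(mol, missingVal=0.0)
    vec = np.array([values[n] for n in DESCRIPTOR_NAMES], dtype=float)
    vec[~np.isfinite(vec)] = 0.0
    return vec


@dataclass
class DescriptorNormalizer:
    """Per-descriptor min-max scaling learned from the base training set.

    Held-out values are clipped to [0,1]; descriptors constant on the
    training set always map to 0.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, raw: np.ndarray) -> np.ndarray:
        span = self.maxs - self.mins
        constant = span == 0
        span = np.where(constant, 1.0, span)
        out = (raw - self.mins) / span
        out = np.where(constant, 0.0, out)
        return np.clip(out, 0.0, 1.0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            n: [float(lo), float(hi)]
            for n, lo, hi in zip(DESCRIPTOR_NAMES, self.mins, self.maxs)
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "DescriptorNormalizer":
        payload = json.loads(Path(path).read_text())
        mins = np.array([payload[n][0] for n in DESCRIPTOR_NAMES])
        maxs = np.array([payload[n][1] for n in DESCRIPTOR_NAMES])
        return cls(mins, maxs)


def fit_descriptor_normalizer(train_vectors: np.ndarray) -> DescriptorNormalizer:
    """Learn per-column min/max from a (n, D) matrix of raw descriptors."""
    mat = np.asarray(train_vectors, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mins = mat.min(axis=0)
    maxs = mat.max(axis=0)
    n_const = int((maxs == mins).sum())
    if n_const:
        logger.info("normalizer: %d constant descriptor columns", n_const)
    return DescriptorNormalizer(mins=mins, maxs=maxs)


def compute_descriptor_vector(
    smiles: str, normalizer: DescriptorNormalizer
) -> np.ndarray:
    """Normalized descriptor vector in [0,1]^D."""
    return normalizer.transform(compute_raw_descriptors(smiles))


# -- molecular graph --------------------------------------------------------

# element vocabulary: 42 named symbols + 1 trailing "other" slot = 43
_ELEMENTS = (
    "C N O S F Cl Br I P B Si Se Te As Al Zn Ca Na K Mg Li Fe Cu Mn Co Ni "
    "Cr Sn Ag Pd Pt Au Hg Ti V Zr Mo W Ru Rh Sb Bi"
).split()
_ELEMENT_INDEX = {s: i for i, s in enumerate(_ELEMENTS)}
_N_ELEMENT_SLOTS = len(_ELEMENTS) + 1  # 43


def _one_hot(value: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[min(value, size - 1)] = 1.0
    return v


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    """65-dim atom descriptor: element, degree, H count, valence, aromaticity,
    formal charge; the natural 66-dim layout truncated to 65."""
    el = np.zeros(_N_ELEMENT_SLOTS)
    el[_ELEMENT_INDEX.get(atom.GetSymbol(), _N_ELEMENT_SLOTS - 1)] = 1.0
    parts = [
        el,                                        # 43
        _one_hot(atom.GetDegree(), 6),             # 6
        _one_hot(atom.GetTotalNumHs(), 5),         # 5
        _one_hot(atom.GetImplicitValence(), 6),    # 6
        np.array([float(atom.GetIsAromatic())]),   # 1
        _one_hot(atom.GetFormalCharge() + 2, 5),   # 5  (charge -2..+2)
    ]
    return np.concatenate(parts)[:N_ATOM_FEATURES]


@dataclass
class GraphFeatures:
    """Zero-padded node matrix and 0/1 adjacency for one molecule."""

    nodes: np.ndarray      # (max_atoms, 65)
    adjacency: np.ndarray  # (max_atoms, max_atoms)
    n_atoms: int


def featurize_graph(smiles: str, max_atoms: int = MAX_ATOMS) -> GraphFeatures:
    """Molecular graph features: one-hot atom rows plus symmetric adjacency.

    Raises :class:`OversizeMoleculeError` beyond ``max_atoms`` heavy atoms —
    oversize molecules are dropped by callers rather than truncated, since
    truncation would corrupt the topology.
    """
    mol = _mol_from_smiles(smiles)
    n = mol.GetNumAtoms()
    if n > max_atoms:
        raise OversizeMoleculeError(
            f"{smiles!r} has {n} heavy atoms > max {max_atoms}"
        )
    nodes = np.zeros((max_atoms, N_ATOM_FEATURES))
    for i, atom in enumerate(mol.GetAtoms()):
        nodes[i] = _atom_features(atom)
    adj = np.zeros((max_atoms, max_atoms))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1.0
    return GraphFeatures(nodes=nodes, adjacency=adj, n_atoms=n)


# -- fingerprints -----------------------------------------------------------


def _bitvect_to_array(fp) -> np.ndarray:
    arr = np.zeros(fp.GetNumBits(), dtype=np.int8)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return arr


def compute_combined_fingerprints(smiles: str) -> np.ndarray:
    """1905-bit vector: 1024 ECFP2 bits followed by 881 substructure-key bits."""
    mol = _mol_from_smiles(smiles)
    ecfp = _bitvect_to_array(_ecfp2_gen.GetFingerprint(mol))
    keys = _bitvect_to_array(Chem.PatternFingerprint(mol, fpSize=N_KEY_BITS))
    return np.concatenate([ecfp, keys])


def compute_fp_index_vector(
    smiles: str,
    n_bits: int = N_ECFP_BITS,
    radius: int = 2,
    max_len: int = MAX_FP_INDICES,
) -> np.ndarray:
    """Sorted 1-based on-bit indices of the Morgan fingerprint, 0-padded.

    The 1-based convention reserves 0 as the padding sentinel for the
    downstream embedding layer. More than ``max_len`` on bits are truncated
    to the first ``max_len`` with a warning.
    """
    mol = _mol_from_smiles(smiles)
    gen = (
        _morgan_r2_gen
        if (n_bits == N_ECFP_BITS and radius == 2)
        else rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    )
    on_bits = sorted(gen.GetFingerprint(mol).GetOnBits())
    if len(on_bits) > max_len:
        warnings.warn(
            f"{smiles!r}: {len(on_bits)} on bits truncated to {max_len}",
            stacklevel=2,
        )
        on_bits = on_bits[:max_len]
    out = np.zeros(max_len, dtype=np.int64)
    out[: len(on_bits)] = np.asarray(on_bits, dtype=np.int64) + 1
    return out


# -- SMILES tokens ----------------------------------------------------------

# bracket atoms, %nn ring closures and two-character organic-subset elements
# are single tokens; everything else is one character per token
_TOKEN_RE = re.compile(r"(\[[^\]]+\]|%\d{2}|Cl|Br|.)")


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into chemically meaningful tokens."""
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise SmilesParseError(f"tokenizer failed on {smiles!r}")
    return tokens


@dataclass
class TokenVocabulary:
    """Token -> integer id map with index 0 reserved for padding."""

    index: dict[str, int]

    PAD = 0
    PAD_TOKEN = "<pad>"

    def __len__(self) -> int:
        return len(self.index) + 1  # + pad

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.index))

    @classmethod
    def from_json(cls, path: str | Path) -> "TokenVocabulary":
        return cls(json.loads(Path(path).read_text()))


def build_token_vocabulary(corpus: Iterable[str]) -> TokenVocabulary:
    """Collect all distinct tokens of a corpus, lexicographically ordered.

    Ids start at 1; id 0 is the padding sentinel and never collides with a
    chemical token.
    """
    tokens: set[str] = set()
    n = 0
    for smi in corpus:
        tokens.update(tokenize_smiles(smi))
        n += 1
    if n == 0:
        raise ValueError("empty corpus")
    return TokenVocabulary({t: i + 1 for i, t in enumerate(sorted(tokens))})


def encode_smiles_tokens(
    smiles: str,
    vocab: TokenVocabulary,
    max_len: int = MAX_TOKENS,
    strict: bool = False,
) -> np.ndarray:
    """Integer token ids right-padded with 0 to ``max_len``.

    Tokens absent from the vocabulary raise in strict mode; in the default
    lenient mode they map to the pad id with a log message, so a frozen
    training vocabulary never crashes at inference time.
    """
    tokens = tokenize_smiles(smiles)
    if len(tokens) > max_len:
        raise OverlengthError(
            f"{smiles!r}: {len(tokens)} tokens > max {max_len}"
        )
    ids = np.zeros(max_len, dtype=np.int64)
    for i, tok in enumerate(tokens):
        if tok in vocab:
            ids[i] = vocab.index[tok]
        elif strict:
            raise KeyError(f"token {tok!r} not in vocabulary")
        else:
            logger.debug("unknown token %r mapped to pad", tok)
    return ids


def decode_token_ids(ids: Sequence[int], vocab: TokenVocabulary) -> str:
    """Inverse of :func:`encode_smiles_tokens` over the non-pad prefix."""
    rev = {i: t for t, i in vocab.index.items()}
    return "".join(rev[i] for i in ids if i != TokenVocabulary.PAD)
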