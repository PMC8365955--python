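"""Tanimoto-based chemical diversity and cross-set similarity analysis.

Diversity is measured on 2048-bit Morgan radius-2 fingerprints (deliberately
distinct from the 1024-bit fingerprints embedded by the models). The mean
pairwise Tanimoto within a set summarizes its internal diversity (lower is
more diverse); per-molecule maxima against a reference set quantify how
close a test set sits to the training data; a seeded t-SNE projects the
fingerprint space to two dimensions for inspection.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.manifold import TSNE

from .dataio import SmilesParseError

__all__ = [
    "fingerprint_2048",
    "tanimoto_similarity",
    "dataset_tanimoto_mean",
    "cross_set_max_similarity",
    "tsne_projection",
]

N_BITS = 2048
_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=N_BITS)


def fingerprint_2048(smiles: str) -> np.ndarray:
    """2048-bit Morgan radius-2 fingerprint as a 0/1 array."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    fp = _gen.GetFingerprint(mol)
    arr = np.zeros(N_BITS, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def tanimoto_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b|; two all-zero fingerprints are identical (1.0)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def _as_matrix(fps: Sequence[np.ndarray]) -> np.ndarray:
    return np.asarray(np.stack([np.asarray(f, dtype=bool) for f in fps]), dtype=np.float64)


def _pairwise_tanimoto(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Tanimoto matrix between fingerprint matrices (rows = molecules)."""
    inter = q @ r.T
    counts_q = q.sum(axis=1)[:, None]
    counts_r = r.sum(axis=1)[None, :]
    union = counts_q + counts_r - inter
    out = np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    return out


def dataset_tanimoto_mean(fps: Sequence[np.ndarray]) -> float | None:
    """Mean Tanimoto over all unordered distinct pairs; None below 2 molecules.

    Exact (no sampling); evaluated blockwise to bound memory on large sets.
    """
    n = len(fps)
    if n < 2:
        return None
    mat = _as_matrix(fps)
    block = 512
    total = 0.0
    for i0 in range(0, n, block):
        qi = mat[i0 : i0 + block]
        sims = _pairwise_tanimoto(qi, mat)
        for local, i in enumerate(range(i0, min(i0 + block, n))):
            total += sims[local, i + 1 :].sum()  # strict upper triangle
    return float(total / (n * (n - 1) / 2))


def cross_set_max_similarity(
    query_fps: Sequence[np.ndarray], reference_fps: Sequence[np.ndarray]
) -> np.ndarray:
    """Per-query maximum Tanimoto against every reference fingerprint."""
    if len(reference_fps) == 0:
        raise ValueError("reference set must be nonempty")
    if len(query_fps) == 0:
        raise ValueError("query set must be nonempty")
    q = _as_matrix(query_fps)
    r = _as_matrix(reference_fps)
    out = np.full(len(query_fps), -np.inf)
    block = 512
    for j0 in range(0, r.shape[0], block):
        sims = _pairwise_tanimoto(q, r[j0 : j0 + block])
        out = np.maximum(out, sims.max(axis=1))
    return out


def tsne_projection(fps: Sequence[np.ndarray], seed: int = 0) -> np.ndarray:
    """Seeded 2-D t-SNE embedding of the fingerprint vectors."""
    n = len(fps)
    if n < 5:
        raise ValueError(f"need at least 5 fingerprints, got {n}")
    mat = _as_matrix(fps)
    perplexity = min(30.0, (n - 1) / 3)
    tsne = TSNE(
        n_components=2,
        random_state=seed,
        perplexity=perplexity,
        init="pca",
    )
    return tsne.fit_transform(mat)
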