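"""Per-protein feature encoders.

Four blocks are produced per protein:

* a pooled embedding vector (mean over residues of an ``L x D`` matrix
  supplied by an :class:`EmbeddingBackend`; ``D = 1024`` for the
  protein-language-model contract),
* conjoint-triad frequencies over a 7-class residue grouping
  (343 = 7^3 components),
* dipeptide composition (400 = 20^2 components),
* Chou's pseudo-amino-acid composition (20 composition + lambda
  sequence-order components, 50 by default).

Triad and dipeptide counts are normalized by the number of windows
(``L-2`` and ``L-1``), so each block is a probability vector regardless
of sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from nifcast.records import STANDARD_AA, ProteinSequence, sanitize_protein

AMINO_ACIDS = STANDARD_AA  # alphabetical one-letter order: ACDEFGHIKLMNPQRSTVWY
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Conjoint-triad residue classes, clustered by side-chain dipole and volume.
TRIAD_CLASSES: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")
_CLASS_OF = {aa: ci for ci, grp in enumerate(TRIAD_CLASSES) for aa in grp}

# ---------------------------------------------------------------------------
# Chou's three physicochemical scales (hydrophobicity, hydrophilicity,
# side-chain mass), the standard tables of the pseudo-amino-acid
# composition scheme.  Each is standardized to zero mean / unit variance
# over the 20 residues before use.
# ---------------------------------------------------------------------------
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def _standardized_scales() -> np.ndarray:
    """3 x 20 array of the property scales, z-scored over the 20 residues."""
    rows = []
    for table in (_HYDROPHOBICITY, _HYDROPHILICITY, _SIDECHAIN_MASS):
        v = np.array([table[aa] for aa in AMINO_ACIDS], dtype=float)
        rows.append((v - v.mean()) / v.std())
    return np.stack(rows)


_SCALES = _standardized_scales()  # shape (3, 20)


@dataclass(frozen=True)
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate feature names")


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Per-residue embedding, shape ``(L, D)``."""

    values: np.ndarray
    backend_id: str = "unknown"

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError(f"embedding must be a non-empty L x D matrix, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite values in embedding")


class EmbeddingBackend(Protocol):
    """Contract for pluggable per-residue embedders."""

    width: int

    def embed(self, seq: ProteinSequence) -> EmbeddingMatrix: ...


def embedding_names(width: int = 1024) -> tuple[str, ...]:
    return tuple(f"emb_{i:04d}" for i in range(1, width + 1))


def mean_pool(m: EmbeddingMatrix) -> FeatureVector:
    """Average an ``L x D`` embedding over residues into a ``1 x D`` vector."""
    vals = np.asarray(m.values, dtype=float).mean(axis=0)
    return FeatureVector(names=embedding_names(vals.shape[0]), values=vals)


def _residue_indices(seq: ProteinSequence | str) -> np.ndarray:
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    residues = sanitize_protein(residues)
    return np.fromiter((_AA_INDEX[a] for a in residues), dtype=np.intp, count=len(residues))


def triad_names() -> tuple[str, ...]:
    return tuple(
        f"ct_{a + 1}{b + 1}{c + 1}" for a in range(7) for b in range(7) for c in range(7)
    )


def triad_encode(seq: ProteinSequence | str) -> FeatureVector:
    """Conjoint-triad frequencies: 343 components, one per class triple."""
    idx = _residue_indices(seq)
    if len(idx) < 3:
        raise ValueError("conjoint-triad encoding needs length >= 3")
    cls = np.fromiter((_CLASS_OF[AMINO_ACIDS[i]] for i in idx), dtype=np.intp, count=len(idx))
    code = cls[:-2] * 49 + cls[1:-1] * 7 + cls[2:]
    counts = np.bincount(code, minlength=343).astype(float)
    return FeatureVector(names=triad_names(), values=counts / (len(idx) - 2))


def dpc_names() -> tuple[str, ...]:
    return tuple(f"dpc_{x}{y}" for x in AMINO_ACIDS for y in AMINO_ACIDS)


def dpc_encode(seq: ProteinSequence | str) -> FeatureVector:
    """Dipeptide composition: 400 adjacent-pair frequencies."""
    idx = _residue_indices(seq)
    if len(idx) < 2:
        raise ValueError("dipeptide encoding needs length >= 2")
    code = idx[:-1] * 20 + idx[1:]
    counts = np.bincount(code, minlength=400).astype(float)
    return FeatureVector(names=dpc_names(), values=counts / (len(idx) - 1))


def paac_names(lam: int = 30) -> tuple[str, ...]:
    return tuple(f"paac_{aa}" for aa in AMINO_ACIDS) + tuple(
        f"paac_lam{j:02d}" for j in range(1, lam + 1)
    )


def paac_encode(seq: ProteinSequence | str, lam: int = 30, w: float = 0.05) -> FeatureVector:
    """Chou's pseudo-amino-acid composition (20 + lam components).

    The first 20 components are amino-acid composition, the last ``lam``
    are sequence-order correlation factors; the whole vector sums to 1.
    theta_j is the average over positions of the correlation function
    Theta(R_i, R_{i+j}) = mean over the three standardized property
    scales of the squared difference.
    """
    idx = _residue_indices(seq)
    L = len(idx)
    if L <= lam:
        raise ValueError(f"pseudo-composition with lambda={lam} needs length > {lam}")
    props = _SCALES[:, idx]  # (3, L)
    theta = np.empty(lam)
    for j in range(1, lam + 1):
        diff = props[:, j:] - props[:, :-j]
        theta[j - 1] = np.mean(diff**2)
    freqs = np.bincount(idx, minlength=20).astype(float)
    freqs /= freqs.sum()
    denom = 1.0 + w * theta.sum()
    values = np.concatenate([freqs, w * theta]) / denom
    return FeatureVector(names=paac_names(lam), values=values)


def encode_protein(
    seq: ProteinSequence | str,
    backend: EmbeddingBackend,
    lam: int = 30,
    w: float = 0.05,
) -> FeatureVector:
    """All four blocks for one protein, concatenated in schema order."""
    if isinstance(seq, str):
        seq = ProteinSequence(id="seq", residues=sanitize_protein(seq))
    pooled = mean_pool(backend.embed(seq))
    blocks = [pooled, triad_encode(seq), dpc_encode(seq), paac_encode(seq, lam=lam, w=w)]
    names = tuple(n for b in blocks for n in b.names)
    values = np.concatenate([b.values for b in blocks])
    return FeatureVector(names=names, values=values)


def pool_protein_encodings(vectors: Sequence[FeatureVector]) -> FeatureVector:
    """Average the encodings of a strain's nitrogenase proteins.

    Each protein is encoded separately and encodings are then averaged,
    so strains with several nitrogenase components are represented by
    the centroid of their per-protein vectors.
    """
    if not vectors:
        raise ValueError("no protein encodings to pool")
    names = vectors[0].names
    for v in vectors[1:]:
        if v.names != names:
            raise ValueError("cannot pool encodings with different schemas")
    return FeatureVector(names=names, values=np.mean([v.values for v in vectors], axis=0))
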