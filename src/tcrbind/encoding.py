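"""Fixed-length numeric encodings of CDR3β/peptide pairs.

Two parallel representations are produced from one scheme:

* integer index vectors (pad 0, residues 1..20 in alphabetical order)
  consumed by the recurrent scorer family, and
* one-hot matrices (positions × 20) consumed by the convolutional family.

Both are post-padded to the scheme's fixed maxima and carry the true
sequence lengths so models can mask padding. The scheme is serialized into
every checkpoint, making prediction independent of ambient configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import AMINO_ACIDS, BindingPair

PAD_INDEX = 0
_AA_TO_INDEX = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}  # 1..20


@dataclass(frozen=True)
class EncodingScheme:
    """Alphabet ordering and fixed maximum lengths for pair encoding."""

    max_len_cdr3: int = 30
    max_len_peptide: int = 30
    alphabet_order: str = AMINO_ACIDS

    def __post_init__(self):
        if len(set(self.alphabet_order)) != 20 or len(self.alphabet_order) != 20:
            raise ValueError("alphabet_order must contain exactly 20 unique symbols")
        if self.max_len_cdr3 < 1 or self.max_len_peptide < 1:
            raise ValueError("maximum lengths must be positive")

    def to_dict(self) -> dict:
        return {
            "max_len_cdr3": self.max_len_cdr3,
            "max_len_peptide": self.max_len_peptide,
            "alphabet_order": self.alphabet_order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingScheme":
        return cls(**d)


@dataclass
class EncodedPair:
    """Index-vector and one-hot views of one pair under a scheme."""

    cdr3_indices: np.ndarray
    peptide_indices: np.ndarray
    cdr3_onehot: np.ndarray
    peptide_onehot: np.ndarray
    true_lengths: tuple[int, int]


def _indices(seq: str, max_len: int, role: str) -> np.ndarray:
    if len(seq) > max_len:
        raise ValueError(f"{role} length {len(seq)} exceeds scheme maximum {max_len}: {seq}")
    out = np.zeros(max_len, dtype=np.int64)
    for i, aa in enumerate(seq):
        out[i] = _AA_TO_INDEX[aa]
    return out


def _onehot(indices: np.ndarray) -> np.ndarray:
    out = np.zeros((indices.shape[0], 20), dtype=np.float64)
    live = indices > 0
    out[np.nonzero(live)[0], indices[live] - 1] = 1.0
    return out


def encode_pair(pair: BindingPair, scheme: EncodingScheme) -> EncodedPair:
    """Encode one pair; deterministic, post-padded, no silent truncation."""
    ci = _indices(pair.cdr3b, scheme.max_len_cdr3, "cdr3")
    pi = _indices(pair.peptide, scheme.max_len_peptide, "peptide")
    return EncodedPair(ci, pi, _onehot(ci), _onehot(pi),
                       (len(pair.cdr3b), len(pair.peptide)))


def encode_dataset(pairs, scheme: EncodingScheme) -> dict[str, np.ndarray]:
    """Vectorized batch encoding of a dataset.

    Returns arrays ``cdr3_idx (n, Lc)``, ``pep_idx (n, Lp)``, ``cdr3_oh``,
    ``pep_oh`` and true-length vectors ``cdr3_len``, ``pep_len``.
    """
    n = len(pairs)
    ci = np.zeros((n, scheme.max_len_cdr3), dtype=np.int64)
    pi = np.zeros((n, scheme.max_len_peptide), dtype=np.int64)
    cl = np.zeros(n, dtype=np.int64)
    pl = np.zeros(n, dtype=np.int64)
    for k, pair in enumerate(pairs):
        ci[k] = _indices(pair.cdr3b, scheme.max_len_cdr3, "cdr3")
        pi[k] = _indices(pair.peptide, scheme.max_len_peptide, "peptide")
        cl[k] = len(pair.cdr3b)
        pl[k] = len(pair.peptide)
    eye = np.eye(21, dtype=np.float64)[:, 1:]  # row 0 (pad) -> all zero
    return {
        "cdr3_idx": ci, "pep_idx": pi,
        "cdr3_oh": eye[ci], "pep_oh": eye[pi],
        "cdr3_len": cl, "pep_len": pl,
    }


def decode_indices(indices: np.ndarray, scheme: EncodingScheme) -> str:
    """Invert an index vector: ``decode(encode(s)) == s``.

    Pads (index 0) may appear only as a suffix; indices above 20 are
    rejected.
    """
    indices = np.asarray(indices)
    if indices.size == 0 or indices[0] == PAD_INDEX:
        raise ValueError("cannot decode an empty sequence (leading pad index)")
    if (indices < 0).any() or (indices > 20).any():
        raise ValueError("index out of range 0..20")
    live = indices != PAD_INDEX
    n = int(live.sum())
    if live[:n].sum() != n:  # a pad occurs before a residue
        pos = int(np.nonzero(~live)[0][0])
        raise ValueError(f"pad before residue at position {pos}")
    return "".join(scheme.alphabet_order[i - 1] for i in indices[:n])
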