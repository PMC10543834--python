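"""Protein sequence → fixed-length integer encoding.

Amino-acid sequences are mapped character-by-character to integer codes
(1-based; 0 is reserved for padding), then cut or right-padded to a fixed
length (default 1000) so that every protein enters the model with the same
shape.  The default alphabet is the 25 letters A–Z without J, covering the
20 canonical residues plus the common ambiguity/non-standard codes
(B, O, U, X, Z); characters outside the alphabet map to the code of 'X'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .errors import InputError

__all__ = [
    "ProteinVocab",
    "EncodedProtein",
    "encode_protein",
    "decode_protein",
    "read_fasta_sequences",
    "DEFAULT_VOCAB",
]

DEFAULT_MAX_LEN = 1000


@dataclass(frozen=True)
class ProteinVocab:
    """Ordered amino-acid alphabet; codes run 1..V, 0 is padding."""

    alphabet: str = "ABCDEFGHIKLMNOPQRSTUVWXYZ"  # 25 letters, alphabetical, no J
    unknown: str = "X"

    def __post_init__(self):
        if len(set(self.alphabet)) != len(self.alphabet):
            raise InputError("vocab alphabet has duplicate characters")
        if self.unknown not in self.alphabet:
            raise InputError("unknown-residue character must be in the alphabet")

    @property
    def size(self) -> int:
        return len(self.alphabet)

    def code(self, residue: str) -> int:
        idx = self.alphabet.find(residue.upper())
        if idx < 0:
            idx = self.alphabet.index(self.unknown)
        return idx + 1


DEFAULT_VOCAB = ProteinVocab()


@dataclass
class EncodedProtein:
    """Fixed-length integer code sequence for one protein."""

    codes: np.ndarray  # (max_len,) int64; 0 = padding
    protein_id: str = ""
    original_length: int = 0

    def validate(self, vocab: ProteinVocab = DEFAULT_VOCAB) -> None:
        nz = self.codes[self.codes != 0]
        if nz.size and (nz.min() < 1 or nz.max() > vocab.size):
            raise InputError("protein code out of vocab range")


def encode_protein(
    sequence: str,
    vocab: ProteinVocab = DEFAULT_VOCAB,
    max_len: int = DEFAULT_MAX_LEN,
    protein_id: str = "",
) -> EncodedProtein:
    """Encode a sequence, truncating to ``max_len`` or right-padding with 0.

    Matching is case-insensitive; characters outside the alphabet map to the
    designated unknown code rather than being dropped.
    """
    if not sequence:
        raise InputError("empty protein sequence")
    if max_len < 1:
        raise InputError("max_len must be >= 1")
    codes = np.zeros(max_len, dtype=np.int64)
    prefix = sequence[:max_len]
    codes[: len(prefix)] = [vocab.code(ch) for ch in prefix]
    return EncodedProtein(codes, protein_id, original_length=len(sequence))


def decode_protein(codes: np.ndarray, vocab: ProteinVocab = DEFAULT_VOCAB) -> str:
    """Inverse of :func:`encode_protein` on the non-padded prefix."""
    codes = np.asarray(codes)
    if codes.size and codes.max() > vocab.size:
        raise InputError("code exceeds vocab size")
    if codes.min(initial=0) < 0:
        raise InputError("negative protein code")
    out = []
    for c in codes:
        if c == 0:
            break
        out.append(vocab.alphabet[int(c) - 1])
    return "".join(out)


def read_fasta_sequences(path) -> dict[str, str]:
    """Read a FASTA file into an id → sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
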