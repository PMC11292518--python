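"""Protein multiple sequence alignments over the 20-amino-acid alphabet.

Residues are stored as integer codes 0..19 in the fixed order
``ARNDCQEGHILKMFPSTWYV`` (the conventional order of empirical replacement
matrices); code 20 is the gap and 21 the unknown/ambiguous state.  Both are
treated as missing data by the likelihood machinery.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from io import StringIO

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP_CODE = 20
UNKNOWN_CODE = 21
_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE["-"] = GAP_CODE
_CODE["."] = GAP_CODE

log = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "GAP_CODE",
    "UNKNOWN_CODE",
    "ProteinAlignment",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "empirical_frequencies",
]


class AlignmentError(ValueError):
    pass


@dataclass
class ProteinAlignment:
    """A gene's MSA: names plus an (n_sequences, L) integer code matrix."""

    gene_id: str
    names: list[str]
    codes: np.ndarray  # (n, L) uint8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.names):
            raise AlignmentError("codes must be (n_sequences, L)")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("duplicate sequence names")
        if self.codes.size and self.codes.max() > UNKNOWN_CODE:
            raise AlignmentError("residue codes out of range")

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def row(self, name: str) -> np.ndarray:
        return self.codes[self.names.index(name)]

    def sequence(self, name: str) -> str:
        lookup = AMINO_ACIDS + "-?"
        return "".join(lookup[c] for c in self.row(name))

    def take_columns(self, cols: np.ndarray) -> "ProteinAlignment":
        return ProteinAlignment(self.gene_id, list(self.names), self.codes[:, cols])


def encode_sequence(seq: str) -> np.ndarray:
    """Map a residue string to integer codes, uppercasing; anything not a
    standard residue or gap becomes the unknown state."""
    out = np.empty(len(seq), dtype=np.uint8)
    n_unknown = 0
    for i, ch in enumerate(seq.upper()):
        code = _CODE.get(ch)
        if code is None:
            code = UNKNOWN_CODE
            n_unknown += 1
        out[i] = code
    if n_unknown:
        log.warning("%d non-standard residue(s) mapped to the unknown state", n_unknown)
    return out


def read_fasta_alignment(text: str, gene_id: str = "gene") -> ProteinAlignment:
    """Parse a FASTA alignment; all records must have equal length."""
    records = list(SeqIO.parse(StringIO(text), "fasta"))
    if not records:
        raise AlignmentError("no FASTA records found")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        bad = [(r.id, len(r.seq)) for r in records]
        raise AlignmentError(f"ragged alignment, lengths per record: {bad}")
    names = [r.id for r in records]
    codes = np.vstack([encode_sequence(str(r.seq)) for r in records])
    return ProteinAlignment(gene_id=gene_id, names=names, codes=codes)


def read_fasta_file(path: str, gene_id: str | None = None) -> ProteinAlignment:
    with open(path) as fh:
        text = fh.read()
    if gene_id is None:
        import os

        gene_id = os.path.splitext(os.path.basename(path))[0]
    return read_fasta_alignment(text, gene_id=gene_id)


def write_fasta_alignment(aln: ProteinAlignment) -> str:
    lookup = AMINO_ACIDS + "-?"
    chunks = []
    for name, row in zip(aln.names, aln.codes):
        seq = "".join(lookup[c] for c in row)
        chunks.append(f">{name}\n{seq}\n")
    return "".join(chunks)


def empirical_frequencies(aln: ProteinAlignment, pseudocount: float = 1e-6) -> np.ndarray:
    """Observed residue proportions over all non-gap, non-unknown cells.

    A small pseudocount is added to every state before renormalising so no
    frequency is exactly zero (the "+F" frequencies of an empirical model
    must be strictly positive).
    """
    flat = aln.codes.ravel()
    counts = np.bincount(flat[flat < GAP_CODE], minlength=20).astype(float)
    total = counts.sum()
    if total == 0:
        raise AlignmentError("alignment has no informative residues (all gap/unknown)")
    freqs = counts / total + pseudocount
    return freqs / freqs.sum()
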