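"""Sequence records, the amino-acid alphabet, and FASTA I/O."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

#: Canonical amino-acid order used for every emission/background vector.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Average composition of proteins (Swiss-Prot release statistics), normalised.
_BG = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}
BACKGROUND = np.array([_BG[a] for a in AMINO_ACIDS], dtype=float)
BACKGROUND /= BACKGROUND.sum()

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """A protein or nucleotide sequence with provenance.

    Attributes
    ----------
    id : unique identifier.
    seq : residue string (uppercase).
    species : optional source species label.
    lineage : optional taxonomic lineage label.
    """

    id: str
    seq: str
    species: str | None = None
    lineage: str | None = None

    def __len__(self) -> int:
        return len(self.seq)

    def with_seq(self, seq: str) -> "SequenceRecord":
        return dataclasses.replace(self, seq=seq)


def encode(seq: str) -> np.ndarray:
    """Encode residues as indices into AMINO_ACIDS; 'X' becomes -1.

    Raises ValueError on any other non-standard symbol.
    """
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq.upper()):
        if ch == "X":
            out[i] = -1
        else:
            try:
                out[i] = AA_INDEX[ch]
            except KeyError:
                raise ValueError(f"non-amino-acid symbol {ch!r} at position {i + 1}")
    return out


def read_fasta(path: str | Path, lineage: str | None = None) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), lineage=lineage)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 80) -> None:
    """Write records as FASTA wrapped at ``wrap`` columns."""
    bio = (_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records)
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


def random_background_seq(length: int, rng: np.random.Generator) -> str:
    """An i.i.d. sequence from the average amino-acid composition."""
    idx = rng.choice(20, size=length, p=BACKGROUND)
    return "".join(AMINO_ACIDS[i] for i in idx)
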