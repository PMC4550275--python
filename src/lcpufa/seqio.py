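"""Sequence records, FASTA I/O, translation and reverse complement.

Every other module consumes the :class:`SeqRecord` defined here.  FASTA
parsing is delegated to Biopython; records are normalised to upper case and
validated against a nucleotide or protein alphabet on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List

from Bio import SeqIO as _BioSeqIO
from Bio.Data import CodonTable as _CodonTable

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")

_STANDARD_TABLE = _CodonTable.unambiguous_dna_by_name["Standard"]
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FASTA_WRAP = 70


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (empty sequence, bad header)."""


class AlphabetError(ValueError):
    """Raised when residues fall outside the declared alphabet."""


@dataclass
class SeqRecord:
    """A named nucleotide or protein sequence.

    Parameters
    ----------
    id : str
        Identifier (FASTA header token before the first whitespace).
    residues : str
        Sequence; upper-cased on construction.
    alphabet : {"nucleotide", "protein"}
        Declared alphabet; residues are validated against it.  If omitted it
        is inferred: sequences drawn entirely from ``ACGTN`` are nucleotide.
    description : str
        Remainder of the FASTA header, may be empty.
    """

    id: str
    residues: str
    alphabet: str = ""
    description: str = field(default="")

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("record with empty id")
        self.residues = self.residues.upper()
        if not self.residues:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        if not self.alphabet:
            self.alphabet = (
                "nucleotide"
                if set(self.residues) <= NUCLEOTIDE_ALPHABET
                else "protein"
            )
        allowed = (
            NUCLEOTIDE_ALPHABET if self.alphabet == "nucleotide" else PROTEIN_ALPHABET
        )
        bad = set(self.residues) - allowed
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: characters {sorted(bad)} not in "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path, alphabet: str = "") -> List[SeqRecord]:
    """Read a multi-record FASTA file.

    One :class:`SeqRecord` per header, input order preserved, wrapped
    sequence lines concatenated, case normalised to upper.  ``alphabet``
    forces the declared alphabet for every record; by default it is inferred
    per record.
    """
    path = Path(path)
    records: List[SeqRecord] = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has no sequence")
        records.append(
            SeqRecord(
                id=rec.id,
                residues=seq,
                alphabet=alphabet,
                description=rec.description[len(rec.id) :].strip(),
            )
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    """Write records as FASTA, sequence lines wrapped at 70 columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), FASTA_WRAP):
                fh.write(rec.residues[i : i + FASTA_WRAP] + "\n")


def revcomp(nt: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    nt = nt.upper()
    bad = set(nt) - NUCLEOTIDE_ALPHABET
    if bad:
        raise AlphabetError(f"non-nucleotide characters {sorted(bad)}")
    return nt.translate(_COMPLEMENT)[::-1]


def translate(nt: str, frame: int = 0) -> str:
    """Translate ``nt`` from ``frame`` (0-2) under the standard genetic code.

    Translation runs to the first in-frame stop codon or the end of the
    sequence; the stop symbol is not included in the output and a trailing
    partial codon is ignored.  Any codon containing ``N`` yields ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    nt = nt.upper()
    bad = set(nt) - NUCLEOTIDE_ALPHABET
    if bad:
        raise AlphabetError(f"non-nucleotide characters {sorted(bad)}")
    out = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            out.append("X")
            continue
        if codon in STOP_CODONS:
            break
        out.append(CODON_TO_AA[codon])
    return "".join(out)
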