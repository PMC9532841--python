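"""Peptide sequence type, validation, and FASTA/TSV I/O.

Sequences are plain one-letter strings restricted to the 20 canonical
amino acids, uppercased on input. The N-terminus is always a free amine;
the C-terminus may be a free acid (default) or an amide.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import CANONICAL_RESIDUES

_CANONICAL = frozenset(CANONICAL_RESIDUES)

FREE_ACID = "free-acid"
AMIDE = "amide"


class SequenceError(ValueError):
    """Raised for malformed or non-canonical peptide sequences."""


@dataclass(frozen=True)
class PeptideSequence:
    """A named peptide in one-letter code with terminal-modification flags.

    Parameters
    ----------
    name : str
        Identifier, unique within a collection.
    residues : str
        One-letter residue codes (ACDEFGHIKLMNPQRSTVWY), length >= 1.
    c_term : str
        ``"free-acid"`` (default) or ``"amide"``.
    parent_name, parent_start : optional provenance for subsequences
        extracted from a longer parent (1-based start in the parent).
    """

    name: str
    residues: str
    c_term: str = FREE_ACID
    parent_name: str | None = field(default=None, compare=False)
    parent_start: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.c_term not in (FREE_ACID, AMIDE):
            raise SequenceError(f"unknown c_term {self.c_term!r}")
        object.__setattr__(self, "residues", _check_residues(self.residues, self.name))

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def with_c_term(self, c_term: str) -> "PeptideSequence":
        return replace(self, c_term=c_term)


def _check_residues(seq: str, name: str = "<sequence>") -> str:
    if not isinstance(seq, str):
        raise SequenceError(f"{name}: sequence must be a string")
    seq = seq.strip().upper()
    if not seq:
        raise SequenceError(f"{name}: empty sequence (length must be >= 1)")
    for pos, res in enumerate(seq, start=1):
        if res not in _CANONICAL:
            raise SequenceError(
                f"{name}: illegal residue {res!r} at position {pos} "
                f"(only {CANONICAL_RESIDUES} allowed)"
            )
    return seq


def validate_sequence(seq: str, name: str = "peptide", c_term: str = FREE_ACID) -> PeptideSequence:
    """Uppercase and validate a raw one-letter string into a PeptideSequence.

    Non-canonical letters (including B, J, O, U, X, Z) are rejected with the
    offending position reported.
    """
    return PeptideSequence(name=name, residues=seq, c_term=c_term)


def parse_fasta(source: Union[str, IO[str]]) -> list[PeptideSequence]:
    """Parse a multi-record FASTA stream (or string) into peptides.

    Record order is preserved; sequences are uppercased and validated.
    Raises :class:`SequenceError` on an empty file, an empty record, or an
    illegal residue (reporting record name and position).
    """
    handle = io.StringIO(source) if isinstance(source, str) else source
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise SequenceError("no FASTA records found")
    peptides = []
    for rec in records:
        peptides.append(validate_sequence(str(rec.seq), name=rec.id))
    return peptides


def read_fasta(path) -> list[PeptideSequence]:
    with open(path) as handle:
        return parse_fasta(handle)


def write_fasta(peptides: Iterable[PeptideSequence], handle: IO[str]) -> None:
    records = [
        SeqRecord(Seq(p.residues), id=p.name, description="") for p in peptides
    ]
    SeqIO.write(records, handle, "fasta-2line")


def fasta_string(peptides: Iterable[PeptideSequence]) -> str:
    buf = io.StringIO()
    write_fasta(peptides, buf)
    return buf.getvalue()


#: Fixed column order of the descriptor table written by the pipeline.
DESCRIPTOR_COLUMNS = [
    "name", "sequence", "length", "Z", "H", "H_pct", "muH",
    "M_avg", "M_mono", "MH_plus",
]


def write_descriptor_table(rows: Iterable[dict], handle: IO[str]) -> None:
    """Write descriptor rows as TSV with the fixed column order."""
    handle.write("\t".join(DESCRIPTOR_COLUMNS) + "\n")
    for row in rows:
        handle.write("\t".join(str(row[c]) for c in DESCRIPTOR_COLUMNS) + "\n")
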