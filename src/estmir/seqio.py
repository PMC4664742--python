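"""FASTA I/O, alphabet normalization and exact-duplicate removal.

Reference mature-miRNA sets are carried in the RNA alphabet and EST /
transcript collections in the DNA alphabet; the ``alphabet`` argument of
:func:`read_fasta` enforces that convention at parse time so no mixed
U/T comparison can happen downstream.  Redundancy removal collapses
byte-identical sequences only (the 100%-identity clustering stage of the
pipeline), keeping the first occurrence as representative.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

ALPHABETS = ("rna", "dna", "any")

_ALLOWED = frozenset("ACGTUN")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class FastaParseError(ValueError):
    """Raised on malformed FASTA input (bad characters, empty or duplicate records)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence.

    ``id`` is the first whitespace-delimited token of the header line;
    ``description`` keeps the remainder.  The sequence is stored uppercase
    over the alphabet {A, C, G, T, U, N}.
    """

    id: str
    sequence: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaParseError("record with empty id")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize(seq: str, alphabet: str) -> str:
    seq = seq.upper()
    if alphabet == "rna":
        return seq.replace("T", "U")
    if alphabet == "dna":
        return seq.replace("U", "T")
    if alphabet == "any":
        return seq
    raise ValueError(f"unknown alphabet {alphabet!r}; expected one of {ALPHABETS}")


def read_fasta(path: str | Path, alphabet: str = "any") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Parameters
    ----------
    path
        FASTA file; multi-line sequences are accepted.
    alphabet
        ``rna`` maps T->U, ``dna`` maps U->T, ``any`` leaves the sequence
        unchanged.  Characters outside {A,C,G,T,U,N} raise
        :class:`FastaParseError` naming the offending record.

    Records are returned in file order.  Duplicate ids raise
    :class:`FastaParseError`: ids must be unique within a collection.
    """
    if alphabet not in ALPHABETS:
        raise ValueError(f"unknown alphabet {alphabet!r}; expected one of {ALPHABETS}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize(str(rec.seq), alphabet)
        if not seq:
            raise FastaParseError(f"record {rec.id!r}: empty sequence")
        if rec.id in seen:
            raise FastaParseError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        try:
            records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
        except FastaParseError:
            raise FastaParseError(
                f"record {rec.id!r}: characters outside alphabet "
                f"{sorted(set(str(rec.seq).upper()) - _ALLOWED)!r}"
            ) from None
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def fasta_string(records: Iterable[SequenceRecord], width: int = 60) -> str:
    """Render records as a FASTA-formatted string (same layout as :func:`write_fasta`)."""
    buf = io.StringIO()
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        buf.write(f">{header}\n")
        for i in range(0, len(rec.sequence), width):
            buf.write(rec.sequence[i : i + width] + "\n")
    return buf.getvalue()


def dedup_identical(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse byte-identical sequences, keeping the first occurrence.

    This is the 100%-identity redundancy-removal stage applied to the
    reference mature-miRNA set before homology search.  Output preserves
    the input order of representatives and the operation is idempotent.
    No substring clustering is performed: shorter isoforms of a longer
    sequence are kept.
    """
    seen: set[str] = set()
    out: list[SequenceRecord] = []
    for rec in records:
        if rec.sequence not in seen:
            seen.add(rec.sequence)
            out.append(rec)
    return out


def reverse_complement(sequence: str, alphabet: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    seq = sequence.upper()
    if alphabet == "dna":
        table, allowed = _DNA_COMPLEMENT, set("ACGTN")
    elif alphabet == "rna":
        table, allowed = _RNA_COMPLEMENT, set("ACGUN")
    else:
        raise ValueError(f"alphabet must be 'dna' or 'rna', got {alphabet!r}")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"invalid {alphabet} characters {sorted(bad)!r}")
    return seq.translate(table)[::-1]


def transcribe(sequence: str) -> str:
    """DNA -> RNA transliteration (T -> U)."""
    return sequence.upper().replace("T", "U")


def back_transcribe(sequence: str) -> str:
    """RNA -> DNA transliteration (U -> T)."""
    return sequence.upper().replace("U", "T")


def read_exclusion_list(path: str | Path) -> set[str]:
    """Read a plain-text id exclusion list: one EST id per line, '#' comments allowed.

    Users who screen candidate precursors against a protein database
    externally can feed the flagged EST ids back in through this file.
    """
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line.split()[0])
    return ids
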