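"""Reading, validating and writing aligned nucleotide sequences.

Sequences are assumed PRE-ALIGNED and co-oriented (forward strand of a
single PCR amplicon, e.g. the ~654 bp Folmer COI fragment); this module
validates equal lengths but never aligns.  Coordinates are 0-based,
half-open throughout the package; user-facing reports print 1-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from coibarcode.errors import (
    AlignmentError,
    DuplicateIdError,
    FastaFormatError,
    InvalidSequenceError,
)

#: IUPAC nucleotide alphabet (post-normalisation; U is stored as T).
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Unambiguous bases; everything else is excluded from pairwise site counts.
UNAMBIGUOUS = frozenset("ACGT")


def normalize_seq(seq: str) -> str:
    """Upper-case a nucleotide string and map U to T.

    Raises
    ------
    InvalidSequenceError
        If the result contains a character outside the IUPAC alphabet,
        or the input is empty.
    """
    norm = seq.upper().replace("U", "T")
    if not norm:
        raise InvalidSequenceError("empty sequence")
    bad = set(norm) - IUPAC_ALPHABET
    if bad:
        raise InvalidSequenceError(
            f"non-IUPAC characters {sorted(bad)} in sequence"
        )
    return norm


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled, aligned nucleotide sequence.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within a dataset.
    seq : str
        Nucleotide text over the IUPAC alphabet; normalised on
        construction (upper-case, U -> T).
    label : str, optional
        Free-text species or cluster tag.
    """

    id: str
    seq: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InvalidSequenceError("record id must be non-empty")
        object.__setattr__(self, "seq", normalize_seq(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length sequence records.

    Invariants: at least two records, all the same length, unique ids.
    """

    records: tuple[SequenceRecord, ...]
    length: int = field(init=False)

    def __init__(self, records: Iterable[SequenceRecord]):
        records = tuple(records)
        if len(records) < 2:
            raise AlignmentError(
                f"an alignment needs at least 2 records, got {len(records)}"
            )
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"records have unequal lengths {sorted(lengths)}"
            )
        seen: set[str] = set()
        for r in records:
            if r.id in seen:
                raise DuplicateIdError(f"duplicate record id {r.id!r}")
            seen.add(r.id)
        object.__setattr__(self, "records", records)
        object.__setattr__(self, "length", lengths.pop())

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def slice(self, start: int, stop: int) -> "Alignment":
        """Coordinate-window subsequence (0-based, half-open) of every record."""
        if not (0 <= start < stop <= self.length):
            raise AlignmentError(
                f"window [{start}, {stop}) outside alignment of length {self.length}"
            )
        return Alignment(
            SequenceRecord(r.id, r.seq[start:stop], r.label) for r in self.records
        )


def _records_from_handle(handle: io.TextIOBase, source: str) -> list[SequenceRecord]:
    try:
        bio_records = list(_BioSeqIO.parse(handle, "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython wording varies
        raise FastaFormatError(f"{source}: {exc}") from exc
    if not bio_records:
        raise FastaFormatError(f"{source}: no FASTA records found")
    out = []
    for rec in bio_records:
        if not rec.id:
            raise FastaFormatError(f"{source}: record with empty header")
        label = rec.description[len(rec.id):].strip() or None
        try:
            out.append(SequenceRecord(rec.id, str(rec.seq), label))
        except InvalidSequenceError as exc:
            raise FastaFormatError(f"{source}: record {rec.id!r}: {exc}") from exc
    return out


def read_fasta(path: str | Path) -> Alignment:
    """Read a multi-record FASTA file as an :class:`Alignment`.

    Records keep file order; lower-case and U are normalised; text after
    the first whitespace in a header becomes the record's ``label``.

    Raises
    ------
    FastaFormatError, DuplicateIdError, AlignmentError
        Distinct diagnostics for malformed records, repeated ids and
        unequal lengths.
    """
    path = Path(path)
    with open(path) as handle:
        return Alignment(_records_from_handle(handle, str(path)))


def read_fasta_string(text: str) -> Alignment:
    """Parse FASTA from an in-memory string (convenience for tests/CLI)."""
    return Alignment(_records_from_handle(io.StringIO(text), "<string>"))


def write_fasta(aln: Alignment, path: str | Path, wrap: int = 70) -> Path:
    """Write an alignment as FASTA; labels go after the id in the header.

    Round-trip contract: ``read_fasta(write_fasta(x)) == x``.
    """
    path = Path(path)
    bio_records = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.label or "")
        for r in aln
    ]
    with open(path, "w") as handle:
        writer = _BioSeqIO.FastaIO.FastaWriter(handle, wrap=wrap or None)
        writer.write_file(bio_records)
    return path


def read_genbank(path: str | Path) -> SequenceRecord:
    """Read a single GenBank flat-file record (convenience for reference
    accessions downloaded separately)."""
    path = Path(path)
    with open(path) as handle:
        records = list(_BioSeqIO.parse(handle, "genbank"))
    if len(records) != 1:
        raise FastaFormatError(
            f"{path}: expected exactly one GenBank record, found {len(records)}"
        )
    rec = records[0]
    organism = rec.annotations.get("organism")
    return SequenceRecord(rec.id, str(rec.seq), organism)
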