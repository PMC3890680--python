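"""Collapse aligned individuals into unique haplotypes with counts.

Exact string identity (after normalisation) defines a haplotype.
Sequences that differ only at ambiguity codes (A vs R at one site) are
kept distinct: the grouping is deterministic and conservative, and users
who want ambiguity-aware merging should resolve codes upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from coibarcode.errors import AlignmentError
from coibarcode.seqio import Alignment, SequenceRecord


@dataclass(frozen=True)
class Haplotype:
    """One unique sequence with the ids of the individuals carrying it."""

    name: str
    seq: str
    members: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HaplotypeTable:
    """Ordered unique haplotypes; counts partition the input records."""

    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        seqs = [h.seq for h in self.haplotypes]
        if len(set(seqs)) != len(seqs):
            raise AlignmentError("haplotype sequences must be pairwise distinct")
        all_members = [m for h in self.haplotypes for m in h.members]
        if len(set(all_members)) != len(all_members):
            raise AlignmentError("a record id appears in more than one haplotype")

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    @property
    def n_individuals(self) -> int:
        return sum(h.count for h in self.haplotypes)

    def names(self) -> list[str]:
        return [h.name for h in self.haplotypes]

    def seqs(self) -> list[str]:
        return [h.seq for h in self.haplotypes]

    def representatives(self) -> Alignment:
        """One record per haplotype, named by haplotype (for trees/digests)."""
        return Alignment(SequenceRecord(h.name, h.seq) for h in self.haplotypes)


def collapse(aln: Alignment) -> HaplotypeTable:
    """Group identical sequences; name haplotypes H1..Hk by first appearance.

    Counts sum to the number of input records and every record id lands
    in exactly one haplotype's member list.
    """
    groups: dict[str, list[str]] = {}
    for rec in aln:
        groups.setdefault(rec.seq, []).append(rec.id)
    haplotypes = tuple(
        Haplotype(f"H{i}", seq, tuple(members))
        for i, (seq, members) in enumerate(groups.items(), start=1)
    )
    return HaplotypeTable(haplotypes)


def haplotype_frequencies(tab: HaplotypeTable) -> list[tuple[str, float]]:
    """Relative frequency of each haplotype among the sampled individuals."""
    total = tab.n_individuals
    return [(h.name, h.count / total) for h in tab]


def write_table_tsv(tab: HaplotypeTable, path: str | Path) -> Path:
    """Write the table as TSV: name, count, member ids (comma-joined), sequence."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("name\tcount\tmembers\tseq\n")
        for h in tab:
            fh.write(f"{h.name}\t{h.count}\t{','.join(h.members)}\t{h.seq}\n")
    return path


def read_table_tsv(path: str | Path) -> HaplotypeTable:
    """Read a table written by :func:`write_table_tsv`."""
    rows: list[Haplotype] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["name", "count", "members", "seq"]:
            raise AlignmentError(f"{path}: not a haplotype table")
        for line in fh:
            name, count, members, seq = line.rstrip("\n").split("\t")
            rows.append(Haplotype(name, seq, tuple(members.split(","))))
    return HaplotypeTable(tuple(rows))
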