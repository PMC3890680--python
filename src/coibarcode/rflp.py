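"""In-silico restriction digestion and diagnostic-enzyme selection.

Digestion is linear (PCR amplicon, no wrap-around) and models the
top-strand cut position only: for the enzymes used here the
double-strand cut sites coincide with the top-strand offsets at gel
resolution, where only fragment LENGTHS matter.  Cut offsets follow the
standard REBASE specificities:

    HinfI  G^ANTC     NlaIII CATG^
    NlaIV  GGN^NCC    ScrFI  CC^NGG

Degeneracy in the recognition SITE is expanded (IUPAC codes); ambiguity
in the SEQUENCE is an error — expanding it would turn one digest into a
set of possible digests and muddy diagnosability.

``to_gel`` maps fragment lists onto what a 2% agarose gel can resolve:
fragments below ``min_visible`` run off or vanish in the smear, and
fragments closer together than ``resolution`` co-migrate as one band.
``diagnostic_enzymes`` then ranks enzymes by whether every gel pattern
of species A differs from every pattern of species B.

``check_conservation`` verifies that a fragment list sums to the
amplicon length — the quickest way to spot partial-digestion artefacts
in reported band sizes.  Partial digestion itself is not simulated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from coibarcode.errors import AmbiguousBaseError, ConfigError
from coibarcode.seqio import IUPAC_ALPHABET, UNAMBIGUOUS

#: IUPAC nucleotide code -> set of unambiguous bases it matches.
IUPAC_EXPAND: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: recognition site (IUPAC, may be
    degenerate) and the top-strand cut offset within the site."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        if len(site) < 4:
            raise ConfigError(f"{self.name}: site must be >= 4 bp, got {site!r}")
        bad = set(site) - (IUPAC_ALPHABET - {"-"})
        if bad:
            raise ConfigError(f"{self.name}: non-IUPAC site characters {sorted(bad)}")
        if not 0 <= self.cut_offset <= len(site):
            raise ConfigError(
                f"{self.name}: cut offset {self.cut_offset} outside [0, {len(site)}]"
            )
        object.__setattr__(self, "site", site)

    def pattern(self) -> re.Pattern[str]:
        """Overlap-tolerant regex for the expanded site (lookahead capture)."""
        body = "".join(
            c if len(IUPAC_EXPAND[c]) == 1 else f"[{IUPAC_EXPAND[c]}]"
            for c in self.site
        )
        return re.compile(f"(?={body})")


#: The four enzymes of the dreissenid COI assay (REBASE specificities).
REGISTRY: dict[str, RestrictionEnzyme] = {
    "HinfI": RestrictionEnzyme("HinfI", "GANTC", 1),
    "NlaIII": RestrictionEnzyme("NlaIII", "CATG", 4),
    "NlaIV": RestrictionEnzyme("NlaIV", "GGNNCC", 3),
    "ScrFI": RestrictionEnzyme("ScrFI", "CCNGG", 2),
}


def read_enzyme_tsv(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """Extend/override the registry from a TSV of (name, site, offset)."""
    enzymes = dict(REGISTRY)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            name, site, offset = line.split("\t")
            enzymes[name] = RestrictionEnzyme(name, site, int(offset))
    return enzymes


def _check_unambiguous(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    for pos, base in enumerate(seq):
        if base not in UNAMBIGUOUS:
            raise AmbiguousBaseError(
                f"ambiguous base {base!r} at position {pos}; digestion needs "
                "an unambiguous A/C/G/T sequence"
            )
    return seq


def find_sites(seq: str, enz: RestrictionEnzyme) -> list[int]:
    """All 0-based start positions where the enzyme's site matches.

    Overlapping matches are all reported; the molecule is linear.
    """
    seq = _check_unambiguous(seq)
    return [m.start() for m in enz.pattern().finditer(seq)]


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DigestResult:
    """Cut positions (0-based, between nucleotides) and fragment lengths
    for one enzyme on one haplotype.  Fragments always sum to the
    sequence length (linear molecule: cuts + 1 fragments)."""

    enzyme: str
    haplotype: str
    cut_positions: tuple[int, ...]
    fragments: tuple[int, ...]


def digest(
    seq: str, enz: RestrictionEnzyme, haplotype: str = "?"
) -> DigestResult:
    """Digest a linear sequence: cuts at match start + offset, then
    fragment lengths as consecutive differences."""
    seq = _check_unambiguous(seq)
    cuts = sorted(
        {
            p + enz.cut_offset
            for p in find_sites(seq, enz)
            if 0 < p + enz.cut_offset < len(seq)
        }
    )
    bounds = [0, *cuts, len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(enz.name, haplotype, tuple(cuts), fragments)


def check_conservation(fragments: Sequence[int], expected_length: int) -> bool:
    """True iff the fragment lengths sum to the amplicon length.

    A False return marks the reported pattern as physically impossible
    for a complete digest — typically a partial-digestion artefact band.
    """
    return sum(fragments) == expected_length


@dataclass(frozen=True)
class GelPattern:
    """Band sizes visible on a gel, descending, after dropping fragments
    below ``min_visible`` and merging co-migrating fragments (within
    ``resolution`` bp of the band's largest member)."""

    bands: tuple[int, ...]
    resolution: int
    min_visible: int

    def indistinguishable_from(self, other: "GelPattern") -> bool:
        """Two lanes look the same when they have the same number of
        bands and every corresponding pair is within the resolution."""
        if len(self.bands) != len(other.bands):
            return False
        res = max(self.resolution, other.resolution)
        return all(abs(a - b) < res for a, b in zip(self.bands, other.bands))


def to_gel(r: DigestResult, resolution: int = 20, min_visible: int = 40) -> GelPattern:
    """Project a digest onto gel bands.

    Fragments below ``min_visible`` are dropped.  The rest are merged
    greedily from the largest down: a fragment joins the current band
    while within ``resolution`` bp of that band's largest member,
    otherwise it opens a new band.  Each band is reported at its largest
    member's length.
    """
    visible = sorted(
        (f for f in r.fragments if f >= min_visible), reverse=True
    )
    bands: list[int] = []
    for frag in visible:
        if bands and bands[-1] - frag <= resolution:
            continue  # co-migrates with the current band's anchor
        bands.append(frag)
    return GelPattern(tuple(bands), resolution, min_visible)


@dataclass(frozen=True)
class EnzymeReport:
    """Diagnosability summary for one enzyme across two species."""

    enzyme: str
    diagnostic: bool
    n_variants_a: int
    n_variants_b: int
    total_bands: int
    patterns_a: tuple[tuple[int, ...], ...]
    patterns_b: tuple[tuple[int, ...], ...]

    @property
    def n_variants(self) -> int:
        return self.n_variants_a + self.n_variants_b


def _unique_patterns(gels: Iterable[GelPattern]) -> list[GelPattern]:
    seen: list[GelPattern] = []
    for g in gels:
        if not any(g.bands == s.bands for s in seen):
            seen.append(g)
    return seen


def diagnostic_enzymes(
    results_a: Mapping[str, Sequence[DigestResult]],
    results_b: Mapping[str, Sequence[DigestResult]],
    resolution: int = 20,
    min_visible: int = 40,
) -> list[EnzymeReport]:
    """Rank enzymes by how cleanly they separate species A from B.

    ``results_a`` / ``results_b`` map enzyme name -> digests of every
    haplotype of that species.  An enzyme is diagnostic iff EVERY
    A-haplotype gel pattern is distinguishable from EVERY B-haplotype
    pattern.  Ranking: diagnostic first, then fewer within-species
    pattern variants (an assay a technician can read from a single
    reference lane), then fewer total bands.
    """
    reports = []
    for enzyme in results_a:
        if enzyme not in results_b:
            continue
        if not results_a[enzyme] or not results_b[enzyme]:
            raise ConfigError(f"{enzyme}: empty digest group")
        gels_a = [to_gel(r, resolution, min_visible) for r in results_a[enzyme]]
        gels_b = [to_gel(r, resolution, min_visible) for r in results_b[enzyme]]
        uniq_a = _unique_patterns(gels_a)
        uniq_b = _unique_patterns(gels_b)
        diagnostic = all(
            not ga.indistinguishable_from(gb) for ga in uniq_a for gb in uniq_b
        )
        reports.append(
            EnzymeReport(
                enzyme=enzyme,
                diagnostic=diagnostic,
                n_variants_a=len(uniq_a),
                n_variants_b=len(uniq_b),
                total_bands=sum(len(g.bands) for g in uniq_a + uniq_b),
                patterns_a=tuple(g.bands for g in uniq_a),
                patterns_b=tuple(g.bands for g in uniq_b),
            )
        )
    return sorted(
        reports,
        key=lambda r: (not r.diagnostic, r.n_variants, r.total_bands, r.enzyme),
    )


def digests_to_tsv(results: Iterable[DigestResult], path: str | Path) -> Path:
    """Write digests as TSV: enzyme, haplotype, 1-based cut positions,
    fragment lengths."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("enzyme\thaplotype\tcuts_1based\tfragments\n")
        for r in results:
            cuts = ",".join(str(c + 1) for c in r.cut_positions)
            frags = ",".join(str(f) for f in r.fragments)
            fh.write(f"{r.enzyme}\t{r.haplotype}\t{cuts}\t{frags}\n")
    return path


def gel_lanes_text(
    gels: Mapping[str, GelPattern], ladder: Sequence[int] = (600, 500, 400, 300, 200, 100, 50)
) -> str:
    """Crude text rendering of gel lanes (largest bands at the top)."""
    lanes = {"ladder": tuple(ladder), **{k: g.bands for k, g in gels.items()}}
    width = max(len(k) for k in lanes) + 2
    lines = ["".join(k.ljust(width) for k in lanes)]
    depth = max(len(v) for v in lanes.values())
    for i in range(depth):
        row = []
        for v in lanes.values():
            row.append((f"{v[i]:>4} —" if i < len(v) else "").ljust(width))
        lines.append("".join(row).rstrip())
    return "\n".join(lines)
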