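"""Kimura 2-parameter pairwise distances among haplotypes.

The K2P model corrects observed differences with separate transition
(P) and transversion (Q) proportions:

    d = -(1/2) * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Sites where either sequence carries a gap or ambiguity code are excluded
pair-by-pair (pairwise deletion, the common distance-software default).
Saturated pairs — where the logarithm's argument is non-positive — are
represented as ``math.inf``: an explicit "greater than any finite
distance" flag, never a silently substituted large number.  Distances
are raw proportions internally; outputs also offer percentages because
barcoding papers print them that way (18.5%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from coibarcode.errors import AlignmentError, IncomparablePairError
from coibarcode.haplotypes import HaplotypeTable
from coibarcode.seqio import UNAMBIGUOUS

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SitePairCounts(NamedTuple):
    """Comparable-site tallies for one sequence pair (inputs to K2P)."""

    n_compared: int
    n_transitions: int
    n_transversions: int


def count_site_pairs(a: str, b: str) -> SitePairCounts:
    """Count comparable sites, transitions and transversions for a pair.

    Only sites where both sequences have an unambiguous A/C/G/T are
    compared; transitions are A<->G and C<->T, transversions every
    purine<->pyrimidine difference.
    """
    if len(a) != len(b):
        raise AlignmentError(
            f"sequences have unequal lengths {len(a)} and {len(b)}"
        )
    n_comp = n_ts = n_tv = 0
    for x, y in zip(a, b):
        if x not in UNAMBIGUOUS or y not in UNAMBIGUOUS:
            continue
        n_comp += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            n_ts += 1
        else:
            n_tv += 1
    return SitePairCounts(n_comp, n_ts, n_tv)


def k2p_distance(c: SitePairCounts) -> float:
    """K2P distance (substitutions/site) from site-pair counts.

    Returns ``math.inf`` when the pair is saturated (1-2P-Q <= 0 or
    1-2Q <= 0, where P and Q are the transition and transversion
    proportions).

    Raises
    ------
    IncomparablePairError
        If no site is comparable (``n_compared == 0``).
    """
    if c.n_compared == 0:
        raise IncomparablePairError("no comparable A/C/G/T sites in pair")
    p = c.n_transitions / c.n_compared
    q = c.n_transversions / c.n_compared
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric K2P distance matrix with haplotype names.

    Entries are substitutions/site; ``math.inf`` marks saturated pairs.
    """

    names: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.names)
        if d.shape != (n, n):
            raise AlignmentError(f"matrix shape {d.shape} does not match {n} names")
        if not np.allclose(np.diag(d), 0.0):
            raise AlignmentError("distance matrix diagonal must be zero")
        finite = np.isfinite(d)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            d[finite & finite.T], d.T[finite & finite.T]
        ):
            raise AlignmentError("distance matrix must be symmetric")
        if np.any(d[finite] < 0):
            raise AlignmentError("distances must be non-negative")
        object.__setattr__(self, "d", d)

    def __len__(self) -> int:
        return len(self.names)

    def get(self, a: str, b: str) -> float:
        i, j = self.names.index(a), self.names.index(b)
        return float(self.d[i, j])

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries, row-major order."""
        iu = np.triu_indices(len(self), k=1)
        return self.d[iu]

    def saturated_pairs(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(len(self), k=1)
        return [
            (self.names[i], self.names[j])
            for i, j in zip(*iu)
            if not np.isfinite(self.d[i, j])
        ]

    def as_percent(self) -> np.ndarray:
        return self.d * 100.0

    def to_phylip(self, path: str | Path) -> Path:
        """Write in PHYLIP square distance format."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"{len(self)}\n")
            for name, row in zip(self.names, self.d):
                vals = " ".join(f"{v:.8f}" for v in row)
                fh.write(f"{name:<10s} {vals}\n")
        return path

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("name\t" + "\t".join(self.names) + "\n")
            for name, row in zip(self.names, self.d):
                fh.write(name + "\t" + "\t".join(f"{v:.8f}" for v in row) + "\n")
        return path


def pairwise_matrix(tab: HaplotypeTable) -> DistanceMatrix:
    """K2P distance matrix over a haplotype table.

    Raises
    ------
    IncomparablePairError
        Naming the offending pair if any pair shares no comparable site.
    """
    names = tuple(tab.names())
    seqs = tab.seqs()
    if len(names) < 2:
        raise AlignmentError("need at least 2 haplotypes for a distance matrix")
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij = k2p_distance(count_site_pairs(seqs[i], seqs[j]))
            except IncomparablePairError as exc:
                raise IncomparablePairError(
                    f"pair ({names[i]}, {names[j]}): {exc}"
                ) from exc
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(names, d)


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a PHYLIP square distance matrix."""
    path = Path(path)
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        names, rows = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if len(names) != n:
        raise AlignmentError(f"{path}: expected {n} rows, found {len(names)}")
    return DistanceMatrix(tuple(names), np.array(rows))
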