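"""Species delimitation from a K2P distance matrix, three ways.

* ``otu_clusters`` — fixed-threshold OTUs: single-linkage chains of
  pairwise distance below a cut-off (3% is the conventional COI value).
* ``barcode_gap`` — one-shot barcode-gap discovery: find the widest
  interval between consecutive distinct pairwise distances; if wide
  enough, split by single-linkage at the gap's lower edge.  This is a
  deliberate simplification of recursive ABGD, adequate when the data
  show one clean gap; the minimum gap width is configurable.
* ``k_theta`` — the K/theta (4x) rule: a cluster pair is distinct when
  the mean between-cluster distance K exceeds ``factor`` times the
  larger of the two mean within-cluster distances theta.  Singleton
  clusters take theta = 0 (the within-distance limit), flagged in the
  report.

The neighbour-joining tree (``nj_tree``) supports the OTU method
visually; on an additive matrix NJ recovers the generating tree exactly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj as _skbio_nj

from coibarcode.distances import DistanceMatrix
from coibarcode.errors import AlignmentError, SaturationError


@dataclass(frozen=True)
class Partition:
    """Non-empty, disjoint clusters of haplotype names covering a matrix."""

    clusters: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        all_names = [n for c in self.clusters for n in c]
        if any(not c for c in self.clusters):
            raise AlignmentError("empty cluster in partition")
        if len(set(all_names)) != len(all_names):
            raise AlignmentError("clusters are not disjoint")

    def __len__(self) -> int:
        return len(self.clusters)

    def names(self) -> frozenset[str]:
        return frozenset().union(*self.clusters)

    def as_sets(self) -> set[frozenset[str]]:
        return set(self.clusters)

    def cluster_of(self, name: str) -> int:
        for i, c in enumerate(self.clusters):
            if name in c:
                return i
        raise KeyError(name)


@dataclass(frozen=True)
class DelimitationReport:
    """Partition plus the metric values that justify it.

    ``metrics`` holds the scalars of the named method only; ``decision``
    maps each cluster index pair to its species-distinct verdict.
    """

    method: str
    partition: Partition
    metrics: dict
    decision: dict[tuple[int, int], bool] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.partition)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_clusters": self.n_clusters,
            "clusters": [sorted(c) for c in self.partition.clusters],
            "metrics": _jsonable(self.metrics),
            "decision": {f"{i}-{j}": v for (i, j), v in self.decision.items()},
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    def summary(self) -> str:
        lines = [f"method: {self.method}", f"clusters: {self.n_clusters}"]
        for i, c in enumerate(self.partition.clusters):
            lines.append(f"  cluster {i + 1}: {', '.join(sorted(c))}")
        for k, v in self.metrics.items():
            lines.append(f"  {k}: {v}")
        for (i, j), verdict in sorted(self.decision.items()):
            word = "distinct" if verdict else "not distinct"
            lines.append(f"  clusters {i + 1} vs {j + 1}: {word}")
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# neighbour joining

@dataclass(frozen=True)
class NJTree:
    """Unrooted NJ tree with haplotype tips and branch lengths
    (substitutions/site).  Negative branch lengths produced by the NJ
    formulas are reported as computed, with a warning, not clamped."""

    tree: TreeNode
    names: tuple[str, ...]

    def to_newick(self) -> str:
        return str(self.tree).strip()

    def write_newick(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_newick() + "\n")
        return path

    def tip_distances(self) -> DistanceMatrix:
        """Path-length (patristic) distances between tips; on an additive
        input matrix these reproduce the input exactly."""
        dm = self.tree.tip_tip_distances(list(self.names))
        return DistanceMatrix(tuple(self.names), np.asarray(dm.data))


def nj_tree(m: DistanceMatrix) -> NJTree:
    """Saitou–Nei neighbour joining on a finite distance matrix.

    Raises
    ------
    SaturationError
        Listing the saturated pairs, if any entry is non-finite.
    AlignmentError
        If the matrix has fewer than 3 names.
    """
    if len(m) < 3:
        raise AlignmentError("neighbour joining needs at least 3 taxa")
    sat = m.saturated_pairs()
    if sat:
        raise SaturationError(f"saturated pairs in matrix: {sat}")
    tree = _skbio_nj(_SkbioDM(m.d, list(m.names)), neg_as_zero=False)
    lengths = [n.length for n in tree.traverse() if n.length is not None]
    if any(l < 0 for l in lengths):
        warnings.warn(
            "NJ produced negative branch lengths (reported unclamped)",
            stacklevel=2,
        )
    return NJTree(tree, m.names)


# ---------------------------------------------------------------------------
# single-linkage helpers

def _single_linkage(m: DistanceMatrix, cutoff: float, strict: bool) -> Partition:
    """Union-find over pairs with d < cutoff (strict) or d <= cutoff."""
    names = m.names
    parent = list(range(len(names)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(len(names)), 2):
        dij = m.d[i, j]
        joined = dij < cutoff if strict else dij <= cutoff
        if joined:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
    groups: dict[int, set[str]] = {}
    for i, name in enumerate(names):
        groups.setdefault(find(i), set()).add(name)
    # order clusters by first appearance of any member in the matrix
    ordered = sorted(groups.values(), key=lambda c: min(names.index(n) for n in c))
    return Partition(tuple(frozenset(c) for c in ordered))


def _min_between(m: DistanceMatrix, p: Partition) -> float:
    best = math.inf
    for i, j in combinations(range(len(m)), 2):
        if p.cluster_of(m.names[i]) != p.cluster_of(m.names[j]):
            best = min(best, m.d[i, j])
    return best


# ---------------------------------------------------------------------------
# the three criteria

def otu_clusters(m: DistanceMatrix, threshold: float = 0.03) -> DelimitationReport:
    """Fixed-threshold OTUs by single linkage: two haplotypes share a
    cluster iff connected by a chain of pairwise distances < threshold."""
    part = _single_linkage(m, threshold, strict=True)
    metrics = {
        "threshold": threshold,
        "min_between_cluster_distance": _min_between(m, part),
    }
    decision = {
        (i, j): True for i, j in combinations(range(len(part)), 2)
    }
    return DelimitationReport("otu_threshold", part, metrics, decision)


def barcode_gap(m: DistanceMatrix, min_gap_width: float = 0.01) -> DelimitationReport:
    """Widest-gap barcode discovery over all pairwise distances.

    Sorts the distinct off-diagonal distances, finds the widest interval
    between consecutive values (ties break toward the lower interval),
    and splits by single linkage at the interval's lower edge if the gap
    is at least ``min_gap_width`` wide; otherwise reports one cluster
    with ``gap_found = False``.
    """
    values = sorted(set(float(v) for v in m.offdiag() if math.isfinite(v)))
    if len(values) < 2:
        raise AlignmentError("need at least 2 distinct pairwise distances")
    widths = [(hi - lo, lo, hi) for lo, hi in zip(values, values[1:])]
    # ties (within float noise) break toward the lower interval: a later
    # interval must be wider by more than 1e-12 to displace the incumbent
    best_width, gap_lo, gap_hi = widths[0]
    for w, lo, hi in widths[1:]:
        if w > best_width + 1e-12:
            best_width, gap_lo, gap_hi = w, lo, hi
    if best_width >= min_gap_width:
        part = _single_linkage(m, gap_lo, strict=False)
        metrics = {
            "gap_found": True,
            "gap_lower": gap_lo,
            "gap_upper": gap_hi,
            "gap_width": best_width,
            "min_gap_width": min_gap_width,
        }
        decision = {(i, j): True for i, j in combinations(range(len(part)), 2)}
    else:
        part = Partition((frozenset(m.names),))
        metrics = {
            "gap_found": False,
            "widest_interval": (gap_lo, gap_hi),
            "gap_width": best_width,
            "min_gap_width": min_gap_width,
        }
        decision = {}
    return DelimitationReport("barcode_gap", part, metrics, decision)


def k_theta(
    m: DistanceMatrix, p: Partition, factor: float = 4.0
) -> DelimitationReport:
    """K/theta rule: clusters i, j are distinct species iff
    K(i, j) > factor * max(theta_i, theta_j), strictly.

    theta is the mean within-cluster pairwise distance (0 for
    singletons, flagged); K the mean between-cluster pairwise distance.
    All thetas, Ks and ratios are reported so alternative conventions
    (mean theta, min K) can be applied by the reader.
    """
    if p.names() != frozenset(m.names):
        raise AlignmentError("partition does not cover the matrix names")
    idx = {name: k for k, name in enumerate(m.names)}

    def mean_within(cluster: frozenset[str]) -> float:
        pairs = list(combinations(sorted(cluster), 2))
        if not pairs:
            return 0.0
        return float(np.mean([m.d[idx[a], idx[b]] for a, b in pairs]))

    thetas = [mean_within(c) for c in p.clusters]
    ks: dict[tuple[int, int], float] = {}
    ratios: dict[tuple[int, int], float] = {}
    decision: dict[tuple[int, int], bool] = {}
    for i, j in combinations(range(len(p)), 2):
        between = [
            m.d[idx[a], idx[b]] for a in p.clusters[i] for b in p.clusters[j]
        ]
        if not between:
            raise AlignmentError(f"no between distances for clusters {i}, {j}")
        k_ij = float(np.mean(between))
        theta_ref = max(thetas[i], thetas[j])
        ks[(i, j)] = k_ij
        ratios[(i, j)] = k_ij / theta_ref if theta_ref > 0 else math.inf
        decision[(i, j)] = k_ij > factor * theta_ref
    metrics = {
        "factor": factor,
        "theta": thetas,
        "singleton_clusters": [i for i, c in enumerate(p.clusters) if len(c) == 1],
        "K": ks,
        "ratio": ratios,
    }
    return DelimitationReport("k_theta", p, metrics, decision)
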