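"""Seedable forward simulator for two-cluster COI-like alignments.

The generator emulates the statistical structure the delimitation
analysis assumes: a 654 bp alignment of 241 individuals collapsing to 7
haplotypes in two clusters, with mean within-cluster K2P divergence
around 0.6% and 0.2% and between-cluster divergence around 18.5% —
the dreissenid situation (quagga cluster Q1–Q2, zebra cluster Z1–Z5).

Substitutions are applied as discrete events under the K2P process:
the event count for a branch of expected length d (substitutions/site)
is Poisson(d * L); each event picks a uniform site (repeat hits
allowed) and mutates it — a transition with odds kappa : 1 over a
transversion, the two possible transversion targets equiprobable.  The
K2P distance estimator is consistent for events-per-site under exactly
this process, so a branch simulated at d has expected measured K2P
distance d.  Pairwise targets are met by halving: two tips evolved d/2
from a common founder sit at expected pairwise distance d.

Everything is driven by one ``numpy.random.Generator``; the same seed
reproduces the same alignment bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from coibarcode.errors import ConfigError
from coibarcode.seqio import Alignment, SequenceRecord

_BASES = "ACGT"
#: target bases by event type, per current base
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: K2P saturation guard for the simulator's divergence targets.
MAX_DIVERGENCE = 0.7


@dataclass(frozen=True)
class ClusterSpec:
    """One species-level cluster: how many haplotypes and how far apart."""

    name: str
    n_haplotypes: int
    within_divergence: float  # expected pairwise K2P within the cluster


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults reproduce the dreissenid two-cluster structure: 654 bp,
    241 individuals, clusters Q (2 haplotypes, 0.6% within) and Z
    (5 haplotypes, 0.2% within), 18.5% between, kappa = 4 (typical
    animal mtDNA transition/transversion odds).
    """

    seed: int = 0
    length: int = 654
    n_individuals: int = 241
    clusters: tuple[ClusterSpec, ...] = (
        ClusterSpec("Q", 2, 0.006),
        ClusterSpec("Z", 5, 0.002),
    )
    between_divergence: float = 0.185
    kappa: float = 4.0
    frequency_spectrum: str = "geometric"

    def __post_init__(self) -> None:
        if self.length < 1 or self.n_individuals < 1:
            raise ConfigError("length and n_individuals must be positive")
        max_within = max(c.within_divergence for c in self.clusters)
        if not max_within < self.between_divergence < MAX_DIVERGENCE:
            raise ConfigError(
                "between_divergence must exceed every within_divergence and "
                f"stay below the saturation bound {MAX_DIVERGENCE}"
            )
        n_haps = sum(c.n_haplotypes for c in self.clusters)
        if n_haps > self.n_individuals:
            raise ConfigError(
                f"{n_haps} haplotypes cannot be allocated to "
                f"{self.n_individuals} individuals"
            )
        if self.frequency_spectrum not in ("geometric", "uniform"):
            raise ConfigError(
                f"unknown frequency spectrum {self.frequency_spectrum!r}"
            )


def evolve(
    seq: str, target_divergence: float, kappa: float, rng: np.random.Generator
) -> str:
    """Evolve a sequence along one branch of expected K2P length
    ``target_divergence`` (substitutions/site), with repeat hits."""
    if not 0.0 <= target_divergence < MAX_DIVERGENCE:
        raise ConfigError(
            f"target divergence {target_divergence} outside [0, {MAX_DIVERGENCE})"
        )
    n_events = int(rng.poisson(target_divergence * len(seq)))
    bases = list(seq)
    p_transition = kappa / (kappa + 1.0)
    for _ in range(n_events):
        site = int(rng.integers(len(bases)))
        cur = bases[site]
        if rng.random() < p_transition:
            bases[site] = _TRANSITION[cur]
        else:
            bases[site] = _TRANSVERSIONS[cur][int(rng.integers(2))]
    return "".join(bases)


def _random_ancestor(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _allocate_counts(
    n_individuals: int, n_haplotypes: int, spectrum: str
) -> list[int]:
    """Deterministic allocation of individuals to haplotypes.

    ``geometric``: weights (1/2)^i, largest-remainder rounding, every
    haplotype sampled at least once.  ``uniform``: as equal as possible.
    """
    if spectrum == "uniform":
        base, extra = divmod(n_individuals, n_haplotypes)
        return [base + (1 if i < extra else 0) for i in range(n_haplotypes)]
    weights = np.array([0.5**i for i in range(n_haplotypes)])
    weights /= weights.sum()
    spare = n_individuals - n_haplotypes  # 1 guaranteed copy each
    ideal = weights * spare
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for i in np.argsort(-remainder, kind="stable")[: spare - counts.sum()]:
        counts[i] += 1
    return [int(c) + 1 for c in counts]


def generate(
    cfg: SimulationConfig,
) -> tuple[Alignment, dict[str, str], dict[str, str]]:
    """Generate one synthetic dataset.

    Returns
    -------
    alignment : Alignment
        ``cfg.n_individuals`` records, ids ``ind0001``...; record labels
        carry the true cluster name.
    truth : dict
        record id -> true cluster name.
    templates : dict
        haplotype template name (e.g. ``Q1``, ``Z3``) -> sequence; the
        alignment contains exactly these distinct sequences.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestor = _random_ancestor(cfg.length, rng)

    templates: dict[str, str] = {}
    template_cluster: dict[str, str] = {}
    for cluster in cfg.clusters:
        founder = evolve(ancestor, cfg.between_divergence / 2.0, cfg.kappa, rng)
        for i in range(cluster.n_haplotypes):
            name = f"{cluster.name}{i + 1}"
            # redraw until distinct: haplotypes are unique by definition
            for _ in range(10_000):
                hap = evolve(
                    founder, cluster.within_divergence / 2.0, cfg.kappa, rng
                )
                if hap not in templates.values():
                    break
            else:  # pragma: no cover - would need a pathological config
                raise ConfigError(
                    f"could not draw a distinct haplotype for {name}"
                )
            templates[name] = hap
            template_cluster[name] = cluster.name

    names = list(templates)
    counts = _allocate_counts(
        cfg.n_individuals, len(names), cfg.frequency_spectrum
    )
    hap_of_individual = np.repeat(np.arange(len(names)), counts)
    rng.shuffle(hap_of_individual)

    records, truth = [], {}
    width = len(str(cfg.n_individuals))
    for k, hap_idx in enumerate(hap_of_individual, start=1):
        hap_name = names[int(hap_idx)]
        rec_id = f"ind{k:0{width}d}"
        records.append(
            SequenceRecord(rec_id, templates[hap_name], template_cluster[hap_name])
        )
        truth[rec_id] = template_cluster[hap_name]
    return Alignment(records), truth, templates


def write_truth_tsv(truth: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id\tcluster\n")
        for rec_id, cluster in truth.items():
            fh.write(f"{rec_id}\t{cluster}\n")
    return path
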