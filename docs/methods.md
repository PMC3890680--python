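# Methods

`coibarcode` implements a distance-based DNA-barcoding workflow for
pre-aligned mitochondrial COI amplicons — the setting in which quagga
(*Dreissena rostriformis bugensis*) and zebra (*D. polymorpha*) mussels
are told apart — together with an in-silico RFLP stage for designing a
sequencing-free diagnostic assay. This note records the models,
defaults and design choices, and what the synthetic tests do and do not
demonstrate.

## Input model and conventions

Inputs are equal-length, co-oriented nucleotide sequences (a single
PCR amplicon sequenced with one primer pair, e.g. the ~654 bp Folmer
COI fragment). The package validates but never aligns; indels are not
modelled. Coordinates are 0-based half-open internally; reports print
1-based positions. Haplotypes are exact string classes: two sequences
differing only at an ambiguity code are distinct haplotypes, because
any merging rule would be arbitrary and non-deterministic in effect;
users who prefer otherwise should resolve ambiguities upstream.

## Distances

Pairwise distances use the Kimura 2-parameter model,

d = −½ · ln[(1 − 2P − Q) · √(1 − 2Q)],

with P and Q the transition and transversion proportions over sites
where **both** sequences carry an unambiguous A/C/G/T (pairwise
deletion — it preserves data relative to complete deletion and matches
common distance-software behaviour). Distances are substitutions/site
internally; percentage output is ×100. When the log argument is
non-positive the pair is *saturated* and the entry is `inf`: an honest
flag that orders above every finite distance in clustering and is a
hard error for tree building. No other substitution models and no
gamma rate heterogeneity are provided; the workflow is defined on K2P.

## Species delimitation

Three criteria run on the same matrix:

* **OTU threshold** (default 0.03, the conventional COI species
  cut-off): single-linkage — haplotypes share an OTU iff connected by a
  chain of distances strictly below the threshold. Single linkage makes
  the monotonicity property exact (raising the threshold never
  increases the cluster count).
* **Barcode gap** (default minimum width 0.01): sort the distinct
  pairwise distances, take the widest interval between consecutive
  values, and split by single linkage at its lower edge if the interval
  is wide enough; otherwise report "no gap" and one cluster. Ties
  within 1e-12 keep the lower interval (splitting earlier is the
  conservative barcoding choice and is deterministic). This is a
  one-shot gap finder, not the recursive ABGD partition sweep — it is
  the right tool when the distance histogram shows one clean gap, which
  is the regime this assay targets.
* **K/θ (4× rule)** (default factor 4): θ per cluster is the mean
  within-cluster pairwise distance (0 for singletons, which are
  flagged), K per cluster pair the mean between-cluster distance; a
  pair is distinct iff K > factor · max(θᵢ, θⱼ), strictly. Comparing
  against the larger θ is the conservative reading of "four times the
  within-cluster distance"; both θ values, K and the ratio are reported
  so a reader can apply the mean-θ or per-cluster variants.

Distance means are unweighted over haplotype pairs, not over
individuals; frequency weighting would let common haplotypes dominate
θ, and the published divergence figures this emulates are
haplotype-level.

The neighbour-joining tree (Saitou–Nei, via scikit-bio) supports the
OTU criterion visually. Negative branch lengths are reported as
computed, with a warning — clamping would silently break the additivity
round-trip that validates the implementation. NJ refuses matrices with
saturated entries, naming the offending pairs.

## Haplotype network

The network is the ε = 0 minimum-spanning network: the union of all
minimum spanning trees of the complete graph under integer Hamming
weights (differences over mutually unambiguous sites). Kruskal runs in
weight groups; an edge is retained iff it bridges two components formed
by strictly lighter edges, and one canonical MST (ties by input order)
is flagged `in_mst`. Exact integer weights remove all tolerance
questions from tie detection. This deliberately replaces median-joining:
no unsampled median nodes are inferred, which preserves the one thing
the network is used for here — assigning haplotype groups to species —
while staying fully deterministic.

## In-silico RFLP

The enzyme registry carries the four assay enzymes with their REBASE
specificities (HinfI G^ANTC, NlaIII CATG^, NlaIV GGN^NCC, ScrFI
CC^NGG), extensible from a TSV. Matching expands IUPAC degeneracy in
the *site*; ambiguity in the *sequence* is an error rather than being
expanded into a pattern set, which would muddy what "two lanes differ"
means. Digestion is linear (amplicons), overlapping sites all cut, and
only the top-strand cut coordinate is modelled — fragment *lengths*,
the only gel-visible quantity, are insensitive to the strand convention
at gel resolution. A consequence worth noting: the mirrored-digest
invariant on a reverse complement is exact only for centrally cutting
palindromic enzymes (NlaIV); for end-cutters like NlaIII the terminal
fragments trade the site length.

The gel model has two knobs, chosen for a 2% agarose mini-gel:
`min_visible` = 40 bp (smaller fragments run off or smear) and
`resolution` = 20 bp (fragments closer than this co-migrate; merging is
greedy from the largest fragment, each band reported at its largest
member). An enzyme is *diagnostic* iff every gel pattern of species A
is distinguishable from every pattern of species B; enzymes are ranked
diagnostic-first, then by fewer within-species pattern variants (an
assay readable from a single reference lane), then fewer bands.

Partial digestion is not simulated. Instead `check_conservation`
verifies that a reported fragment list sums to the amplicon length;
the two published dreissenid lanes that fail it (the NlaIV Z5 lane with
its extra ~200 bp band, and the NlaIII Z sizes) are exactly the ones
best explained as gel-reading artefacts, and the package reproduces
that diagnosis rather than attempting to reconcile the numbers.

## Synthetic data

`synth.generate` emulates the study conditions the analysis assumes:
654 bp, 241 individuals, 7 haplotypes in two clusters (Q: 2 haplotypes
at 0.6% within-divergence; Z: 5 at 0.2%), 18.5% between-cluster K2P
divergence, transition/transversion odds κ = 4 (a typical animal mtDNA
value). Substitutions are discrete events: a branch of expected length
d gets Poisson(d·L) events, each at a uniform site (repeat hits
allowed), transition with odds κ:1 and the two transversion targets
equiprobable. The K2P estimator is consistent for events-per-site under
this process, so branch targets calibrate directly; pairwise targets
are met by placing each tip at half the target from the shared founder
or ancestor.

Known, accepted deviations of the simulated truth from the nominal
parameters, measured over 200 seeds: between-cluster haplotype pairs
average ≈19.0% rather than 18.5% because the two tip branches add to
the founder split; the Z-cluster within-divergence averages ≈0.34%
rather than 0.2% because five haplotypes are forced to be distinct
(redraw until unique), which zero-truncates the smallest branches.
Both effects push *away* from the delimitation decision boundary far
less than the 18.5% vs 0.6% contrast itself, so they do not affect any
conclusion the tests draw. The per-haplotype frequency spectrum is not
published; the default is a deterministic geometric allocation
(weights ½ⁱ, largest-remainder, every haplotype sampled at least once),
an arbitrary but reproducible choice, with a uniform alternative.

What passing synthetic tests show: the pipeline recovers a two-species
structure reliably when a clean barcode gap exists at the published
divergence scale, and every algorithmic component matches its
independent oracle. What they do not show: robustness to alignment
error, indels, heteroplasmy, NUMTs, incomplete lineage sorting, or
divergence regimes without a gap — real-data concerns outside this
package's model.

## Numerical and testing choices

Test and acceptance problem sizes (20 seeded replicates for the
delimitation reliability checks; 200 Monte-Carlo branches for simulator
calibration; 1000 random 654-mers for the digestion oracle) were chosen
as the smallest sizes at which the sampling error of each checked
quantity is comfortably below its assertion band. NJ round-trips are
asserted to 1e-9 on additive matrices of 4–12 leaves against a
tree-construction oracle independent of the NJ code. All randomness
flows through seeded `numpy.random.Generator` instances; the pipeline
summary JSON contains no timestamps, so identical configurations
produce byte-identical output.

## Limitations

Single-locus, distance-based delimitation only — no coalescent or
tree-model methods (GMYC/bPTP), no bootstrap support, no recursive
ABGD. The RFLP stage models complete digests of perfect amplicons; it
flags, but does not generate, partial-digest artefacts. GenBank
fetching is deliberately outside the pipeline (a helper script
documents the external cross-check).
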