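# Methods

This note documents the models, rules and numerical choices behind
`magniche`, the assumptions they make, and what the synthetic-data tests do
and do not demonstrate about real data.

## Coordinates and containers

Genomic coordinates are 1-based and inclusive (GFF3 native). Gene order on
a contig is a 0-based, gap-free index assigned by ascending start
coordinate; all locus detection operates on these indices, never on base
pairs, so intergenic distances play no role. Strand is stored but ignored
by every downstream rule. The central container is the *gene table*:
ordered genes per contig, each carrying a set of `(category, family)`
labels with categories GH, PL, CE, CBM, GT, SULFATASE, PEPTIDASE, SUSC,
SUSD, TRANSPORTER.

## Annotation consensus

Seven evidence channels are filtered independently at their database's
threshold: dbCAN HMMs at E ≤ 1e−5; CAZy blastp at E ≤ 1e−20 with percent
identity ≥ 30 and query coverage ≥ 40 (both required; standard 12-column
blast tables carry no coverage, so CAZy tables must include a 13th
qcovhsp-style column); SulfAtlas and MEROPS blastp at E ≤ 1e−4; the Pfam
sulfatase HMM (PF00884) and the Pfam SusD HMMs (PF12741/PF12771/PF14322/
PF07980) at E ≤ 1e−5; the 15 TIGRFAM TonB-dependent-transporter HMMs at
E ≤ 1e−10, with any-hit semantics across profiles.

Per gene and channel, the best hit is the one with the lowest E-value
(ties: higher bit score, then lexicographically smallest family), giving
deterministic single-family-per-channel semantics. A CAZyme label is
emitted only when the best dbCAN and best CAZy families agree after
stripping the dbCAN subfamily suffix (GH16_3 vs GH16 agree); the dbCAN
subfamily form is reported, because subfamily resolution is what separates,
e.g., laminarinase-like GH16_3 from the rest of GH16. Sulfatase labels
accept either evidence channel by default (`sulfatase_mode="both"` requires
agreement); peptidase, SusC and SusD labels accept any surviving hit.
GT labels pass the same agreement rule but are excluded from all
degradative sets. TRANSPORTER labels come from a generic free-text
annotation channel and bypass the hit machinery entirely.

Filtering is idempotent and label assignment is monotone in evidence
(adding a surviving hit never removes a label); both are enforced by
property tests.

## PUL detection

Substrate-utilisation genes are defined as GH/PL/CE/CBM, sulfatases, SusC
and SusD; degradative CAZymes as GH/PL/CE (CBMs bind, GTs synthesise).
Chains are maximal runs of substrate genes in which consecutive substrate
genes are separated by at most `max_gap = 6` non-substrate genes; spans
start and end on substrate genes, and the gap rule is applied to both call
classes so that one region-growing pass produces contiguous, testable
loci. Each chain yields at most one call:

* **canonical** — the chain contains at least one SusC/SusD pair (adjacent
  genes, either order, strand-agnostic, greedy left-to-right pairing so a
  gene joins at most one pair) and ≥ `min_degradative = 2` degradative
  genes;
* **non-canonical** — otherwise, if it contains ≥ `min_chain = 3`
  substrate genes.

Chains are truncated silently at contig edges; no cross-contig stitching is
attempted. Substrate prediction replaces manual curation with three
archetype signatures checked in fixed priority order (alginate >
laminarin > α-fucan): ≥ 2 genes from PL6/PL7/PL17 (base-family
comparison); a GH16_3 (exact subfamily) together with a GH3; a GH29
together with ≥ 2 sulfatase genes. Unmatched loci carry no substrate.

The caller is verified against an independent brute-force oracle that
classifies every maximal valid window, exhaustively over all 6-symbol label
sequences up to length 8 plus seeded random length-30 sequences.

## Dereplication and genus summaries

Species clustering is greedy: genomes are ranked by the dRep-style quality
score Q = completeness − 5 × contamination (ties: larger assembly, then
id); the best unassigned genome seeds a cluster and absorbs every
unassigned genome with ANI ≥ 95 % (inclusive boundary). Missing matrix
entries — all-vs-all ANI tools omit distant pairs — count as below
threshold. Representatives are therefore pairwise below threshold and the
output partitions the genome set.

Genus-level values average over the three most complete genomes of the
genus (ties: lower contamination, then larger assembly); densities are
computed per genome as count/Mbp and then averaged, never pooled. "Family
conserved in a genus" means presence (count ≥ 1) in every selected genome.
Display rounding (densities and PUL counts to integers, sizes to two
decimals, GC to integers) happens only at formatting time. Preference
ratios are `1:x` with x = other/GH rounded **half-up** to one decimal and a
trailing `.0` dropped; half-up at one decimal is the convention that
reproduces all twelve published NS5 ratio cells from their integer density
cells, and ratios can be computed from unrounded means (default) or from
the rounded integers (reproduction mode).

## Abundance statistics

RPKM uses total sample reads in the denominator (library-size
normalisation for cross-sample comparability), and genome length is the
sum of contig lengths. Breadth is the percentage of positions with depth
≥ 1. TAD removes `floor(trim × n)` lowest and highest depth values before
averaging; the truncation fraction defaults to 10 % per tail (TAD80) and is
configurable, since published usage varies. The 0.25-RPKM presence
threshold is inclusive and *flags* records rather than deleting them; the
companion breadth observation (> 40 % coverage at that threshold) is
treated as empirical, with an optional minimum-breadth filter. Pearson
correlations are computed between RPKM and log10(parameter) over samples
that pass the threshold and have strictly positive parameter values
(non-positive values are excluded rather than pseudocounted); constant
series and n < 3 return an absent result with a reason. Oligotype
recruitment implements only the 100 %-identity contract — exact substring
on the forward or reverse-complement strand — and refuses lower thresholds,
which need a real read mapper.

## Repertoire dissimilarity and ordination

Bray-Curtis uses raw counts (no standardisation; a normalisation flag
exists) with BC = 1 − 2Σmin/(Σx + Σy); a pair of all-zero profiles is
defined as 0 with a warning. Hierarchical clustering is scipy average
linkage (UPGMA) by default, with item ids sorted lexicographically first so
equal-distance ties resolve deterministically; merge heights are
non-decreasing and the dendrogram exports to newick. NMDS is non-metric
SMACOF with isotonic regression (scikit-learn), reporting Kruskal
stress-1; runs are reproducible given (seed, restarts = 4), with
max_iter = 300 and tolerance 1e−6.

## Consensus trees

Bipartitions are canonicalised as the leaf side not containing the
lexicographically smallest leaf, making splits comparable across rootings.
The "groups stable across all inference methods" reading is implemented as
strict consensus — exactly the intersection of the inputs' bipartition
sets, rebuilt into a tree with conflicting regions collapsed to
polytomies — with a majority-rule (> 50 %) mode for comparison. Branch
lengths and supports are dropped. The in-package construction is
cross-checked against dendropy's consensus machinery in the tests.

## Synthetic data: what it emulates and what it does not

Defaults encode the study conditions the pipeline targets: 4 genera × 3
species × 2 genomes, genome sizes 1.17–2.05 Mbp, two planted PULs per
genome cycling through the archetypes, a 2 % background annotation rate,
ANI blocks at 96–99 % within species / 80–94 % within genus / 70–79 %
between genera, 20 samples of 10⁶ reads, and six trees over 12 taxa with
two planted stable clades (fixed internal structure, so their internal
splits are stable too).

Generator guarantees that real data do not offer: background substrate
genes are rejection-placed at least 7 gene positions from any other
substrate gene, so they can never merge chains or form accidental loci and
the planted PUL truth is exact; hit tables are constructed so that,
noise-free, the annotation round trip is an identity; decoy hits sit just
outside the thresholds (a 10× E-value margin, or identity/coverage below
the floors). Mapped-read counts are Poisson around the planted-RPKM
expectation and depth profiles are gamma-Poisson (overdispersion 0.3) at a
fixed resolution of 2000 positions per genome — breadth and TAD are
per-position statistics, so resolution affects only sampling noise. One
designated genome responds log-linearly to temperature (slope 2.0 per
log10 unit, noise SD 0.05) for correlation-recovery checks. Gene sequences
are not simulated; FASTA output is stub sequence, and only the oligotype
matcher receives real random sequences with planted substrings.

Passing tests therefore demonstrate the correctness of the rules and
statistics under controlled conditions, not robustness to fragmented
assemblies, chimeric bins, overlapping loci or annotation biases in real
MAGs.

## Problem sizes and degenerate inputs

The default test and acceptance runs use the study-condition bundle
(24 genomes, ~31k genes), exhaustive PUL enumeration to length 8 in the
test suite and length 6 in the acceptance script, 100 random tree sets, and
20-seed stochastic replicates. Degenerate inputs are defined, not silent:
empty depth vectors, zero genome length, zero total reads, k ≥ n
ordinations, empty genome-id lists and mismatched leaf sets raise errors;
singleton clusters report intra-cluster statistics as absent rather than
zero; a zero GH density makes a ratio "NA".

## Known limitations

* The CAZy agreement rule evaluates only each channel's best family; a
  gene with two genuine CAZyme domains receives at most one CAZyme label.
* No operon or promoter model: PUL spans are index intervals, and loci
  split across contigs are counted twice or missed.
* NMDS stress depends on the restart budget; pathological matrices may
  need more than 4 restarts.
* The greedy dereplication depends on the quality ranking when ANI values
  straddle the threshold; the representative-selection criterion is a
  documented convention, not an inference.
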