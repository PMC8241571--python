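# Methods

This note records the models and procedures mgvkit implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the published procedure left
the design open.

## Scope and division of labour

The toolkit owns the arithmetic *between* external tools, not the tools
themselves. Gene calling, HMM and protein similarity searches, CRISPR array
detection, completeness estimation, rRNA search and maximum-likelihood tree
inference are all consumed as tables (12-column tabular hits, GFF3-like
gene tables, array/spacer tables, newick trees). Two built-in stand-ins
exist so the bespoke logic is testable without external binaries: a
k-mer-seeded ungapped local aligner for small genomes and a naive
longest-ORF gene scorer. Both are deliberately simple and are documented
below with their limits.

## Viral classification

A contig is described by four signatures: counts of proteins whose top HMM
hit (bit-score, e-value < 1e-10) is viral or microbial, a nucleotide score
in [0, 1] from a pluggable scorer, and the strand switch rate (adjacent
opposite-strand gene pairs divided by gene count; 0 for fewer than two
genes). Classification applies, per fragment-length class, a disjunction of
up to five clauses of inclusive thresholds (>= for minimums, <= for
maximums). Length classes are {1, 2, 5, 10, 20, 50, 100} kb; a contig maps
to the largest class at or below its length and sub-1 kb contigs are
rejected. Ties in top bit-score across the viral and microbial databases
resolve to viral: sensitivity is cheap here because specificity is enforced
downstream by the benchmark score, `score = TPR − 50 × FPR`, whose
false-positive weight reflects that bulk metagenomes are mostly cellular.

The grid search evaluates the full Cartesian product of candidate
thresholds per signature (a grid entry of `None` leaves that threshold
unset) against labelled fragments, vectorised over the fragment feature
matrix, and keeps the five best clauses per length class. Equal scores are
ordered by the clause's threshold tuple (unset sorting last), making the
selection reproducible. The shipped default rule set is data, not code: it
encodes the qualitative logic with plausible values and is meant to be
re-derived on any benchmark via the harness.

## Quality control

Terminal repeats are exact string matches between a prefix and a suffix
(direct) or the reverse complement of the suffix (inverted), scanned from
min(length/2, 5000) bp down to the 20 bp minimum; N never matches. When a
terminal repeat qualifies as both (palindromic repeats), the direct reading
is reported. Large intragenomic repeats are detected by exact
self-comparison: every 100-mer occurring more than once marks its
occurrence intervals, and the contig is flagged when the interval union
spans strictly more than 30% of its length. Tiers partition completeness
as: complete (closure evidence — DTR, ITR or provirus boundaries — and
completeness > 90), high (> 90), medium (50–90, inclusive at both ends),
low (< 50), undetermined (no estimate). The 50–90 band is inclusive at both
ends by design; the corresponding catalogue selection filter is therefore
"completeness >= 50" in this implementation. Provirus trimming returns the
inclusive 1-based subsequence with a deterministic id suffix; trimming the
full range is the identity, which makes it idempotent.

## Alternative genetic codes

Candidate codes are 11 (stops TAA/TAG/TGA), 4 (TGA recoded; translation
tables 4 and 25 both reassign TGA and are collapsed into the single label
4), 15 (TAG recoded) and 90 (TAA recoded). Only contigs longer than 10 kb
with GC strictly below 50% are evaluated: stop codons are AT-rich, so
low-GC genomes are where in-frame stop statistics are informative, and
short contigs produce unstable score sums. Per code, per-gene coding scores
are summed over the contig; an alternative code is called when its total is
the global maximum and at least 10% greater than code 11's. The margin is
always measured against the standard code, not the runner-up, and is
compared as a ratio (`alt/standard >= 1.10`, with a 1e-12 float guard) so
the decision is scale-invariant and exact at the boundary.

The shipped naive scorer finds maximal stop-free codon runs in all six
frames and scores each ORF by its length in codons, keeping ORFs of at
least 30 codons. It exists for testing only: it has no start-codon model,
no RBS model and no translation statistics.

## Species-level clustering

ANI between two genomes is the alignment-length-weighted mean percent
identity over local alignments; AF is the union of alignment intervals on
the shorter genome divided by its length. Alignments below 90% identity are
discarded first, mirroring the identity floor of the external search the
hit tables come from (tests that measure the aligner itself disable the
floor). Dereplication removes exact duplicates and exact substrings of
longer retained sequences, reverse-complement aware by default since
assemblers emit either strand. Greedy clustering sorts genomes by
decreasing length (ties by id), takes the longest unassigned genome as a
new centroid, and assigns every unassigned genome within 95% ANI and 85% AF
of the centroid (inclusive); members are never reassigned, so the result is
a partition and is invariant to input order.

The built-in aligner seeds on exact 15-mers, groups seeds by diagonal, and
extracts maximal ungapped segments along each diagonal by a linear
Kadane-style scan (match +1, mismatch −1, X-drop 20, minimum segment score
25), on both strands, then removes query-interval duplicates keeping the
highest-scoring segment. It handles the substitution-dominated divergence
regime that species-level thresholds operate in; it does not model indels
and is capped at 100 kb per sequence. Against a full Smith–Waterman oracle
it agrees to within 0.5 ANI points on kilobase-scale pairs up to ~12%
divergence (enforced by the acceptance suite).

## Genus/family clustering

Shared genes between two genomes are reciprocal best hits by bit-score
among protein hits with e-value < 1e-5 (ties resolve to the
lexicographically smaller partner). AAI is the unweighted mean identity
over shared pairs; the shared fraction divides by the smaller gene count,
making it symmetric and robust to fragmentation. Edges are kept at >= 20%
AAI and >= 10% shared genes for family rank, >= 50% and >= 20% for genus
rank, and weighted `aai × shared_fraction / 100` — the procedure that
produced the rank thresholds did not specify reciprocality or a weighting,
so both are configurable with these defaults.

Markov clustering is implemented directly on the dense column-stochastic
matrix: alternate expansion (matrix squaring) and inflation (entrywise
power, default 1.2 for family and 2.0 for genus, then column
renormalisation), pruning entries below 1e-5, until the iterate changes by
less than 1e-6 (at most 100 iterations; non-convergence returns the last
iterate with a warning). Clusters are read from attractors (nodes with
non-zero diagonal), merging overlapping attractor supports. Self-loops are
weighted as each node's maximum incident edge weight rather than a fixed
unit: a unit loop is negligible next to heavy edge weights, leaving the
two-node random walk nearly periodic so that expansion concentrates mass on
the diagonal and genuine pairs shatter into singletons.

## Consensus taxonomy

Hits must cover >= 50% of both query and subject at e-value <= 1e-5. Per
protein and rank, the top bit-score hit's taxon transfers; when the top hit
lacks the rank, the best subsequent hit carrying it with bit-score >= 0.75×
the top supplies it ("within 25% of the top hit" read as a lower bound).
Genome consensus walks ranks from most specific to most general and assigns
the first rank where the modal taxon holds > 70% of the bit-score-weighted
mass among proteins annotated at that rank — unannotated proteins are
excluded from the denominator — subject to the rank minimums (family: >= 2
proteins with > 30% identity; genus: >= 3 proteins with > 40% mean
identity, identity being the transferring hit's percent identity).
More-general ranks are inherited from the best supporting hit's lineage.
Modal ties break to the lexicographically smaller taxon with a logged
warning. The decision is invariant under uniform bit-score scaling.

Host consensus reuses the same machinery with the prokaryotic rank ladder,
unit weights (spacer and genome-match connections count equally — their
relative reliability is not quantified, so no weighting is presumed) and no
rank minimums.

## CRISPR spacer matching

A spacer matches a virus when an end-trimmed core of the spacer covering at
least 95% of its length aligns to either strand with at most one combined
mismatch or gap. Matching enumerates the edit types directly over each trim
variant: exact occurrences, Hamming-distance-1 windows, single-deletion
patterns and single-insertion windows, all vectorised; overlapping matches
collapse to the fewest-edit, leftmost representative. The test suite proves
exact agreement with an independent semi-global DP edit-distance oracle.
Note the coverage rule composes with the edit budget: trimming one terminal
base *and* spending one interior edit is a legal match for a 32-mer, so the
generator plants mismatches strictly interior to the trim fringe to keep
planted truth labels exact.

## Phylogenetic utilities

Columns with >= 50% gaps are removed per marker before concatenation;
genomes missing a marker receive an all-gap block; genomes need >= 3
markers and data at strictly more than 5% of alignment columns to be
retained. PD of a tip subset is the sum of lengths of branches with at
least one subset tip among their descendants on the rooted tree — chosen
over unrooted readings because it makes PD(all tips) equal the total branch
length, the normalisation used when quoting PD coverage shares. Midpoint
rooting delegates to dendropy and is idempotent up to representation.
Core-SNP matrices treat gap and N as missing and count substitutions only;
the position coverage filter (>= 50% of genomes) runs before the genome
data filter (>= 50% of retained positions), in that order.

## The synthetic world

Generators are pure functions of their arguments and seed (byte-identical
across runs). They emulate the *statistical signatures* the pipeline
exploits, not real sequence content: classification operates downstream of
the external search tools, so fixtures plant hit-label compositions, strand
runs and composition scores rather than homology.

* Mock benchmark: 2,000 fragments per category at each of the seven lengths
  by default, six viral categories and two non-viral, mirroring the scale
  of the published in-silico benchmark. Viral fragments draw ~60% viral hit
  labels, strand switches at rate 0.05 and Beta(8,2) nucleotide scores;
  non-viral fragments the converse (3% viral labels, switch rate 0.4,
  Beta(2,8)); gene counts ~1/kb. These rates were fixed once as plausible
  for gut phage versus bacterial contigs; the classes deliberately overlap
  at 1 kb, where single-gene fragments are genuinely ambiguous. A
  `separable` variant (>= 5 viral hits and no microbial hits on every viral
  fragment) provides the regime where a correct grid search must reach
  score 100. Tests and the acceptance script scale `n_per_category` down
  (25–200) to stay within their time budgets; the statistical conclusions
  do not depend on the count.
* Genome pairs: i.i.d. substitutions at a stated rate (each chosen site
  changes base), so expected identity is exactly 100·(1−d); no indels, no
  rearrangements, no mutation-rate heterogeneity.
* Recoded genomes: genes are chains of AT-biased random sense codons
  interleaved with a fixed 16-codon "frame-blocker" cassette whose five
  wrong readings (both shifted forward frames and all reverse frames) each
  contain at least two distinct stop-codon types near both ends. This
  bounds spurious out-of-frame ORFs under *every* candidate code —
  without it, permissive codes accumulate systematically longer frame
  noise and the naive scorer miscalls even standard-code genomes. Recoded
  stops are inserted at segment boundaries (~24 codons apart) so
  standard-code fragments fall below the scorer's 30-codon minimum, and
  each gene ends with TAA+TAG+TGA so no code reads through gene ends.
* Spacer plantings: 32-mers copied from the virus (half reverse-strand)
  with the requested number of interior substitutions.

A green test on these fixtures establishes the correctness of the
arithmetic and decision rules; it does not establish sensitivity on real
sequence data, which depends on the external search tools.

## Known limitations

* The built-in aligner is ungapped; genomes that diverge by indels or
  rearrangement need an external search to feed `pairwise_ani`.
* The naive ORF scorer is a test harness, not a gene caller; production
  use of the genetic-code comparison should plug in a real caller's
  per-gene coding scores.
* Dense-matrix MCL is O(n³) per iteration; it is intended for the
  representative-genome graphs that enter genus/family clustering, not for
  millions of nodes.
* Dereplication is exact-substring only (by definition of the 100%/100%
  criterion); near-duplicates are left to vOTU clustering.
* The published tuned cutoff table for the classifier is supplementary
  material not shipped here; the default rule set is a plausible stand-in
  and the benchmark harness exists to re-derive cutoffs on any benchmark.
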