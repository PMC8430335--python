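# Methods

`lrmine` re-implements, as a tested pipeline, the bespoke computations of a
long-read (CCS/HiFi) versus short-read marine metagenomics workflow:
ORF-length read-quality statistics, consensus taxonomy, RPKG coverage,
composition+coverage binning with a marker-tally quality rule, fragment
ANI, and flexible-genome feature mining, exercised end-to-end on a
ground-truthed synthetic community. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not show about real data.

## The ORF-length error proxy

CCS reads carry no per-base quality scores, so read accuracy is inferred
from coding statistics: substitution errors occasionally convert a sense
codon into a stop, and indels shift the frame into stop-containing
sequence, so the mean length of called proteins falls — and their number
per megabase rises — with the per-base error rate ε.

The caller (`orf_stats.call_orfs`) is a deterministic six-frame
stop-to-stop scanner (stops TAA/TAG/TGA, starts ATG/GTG/TTG, translation
table 11, default minimum 30 aa, edge-truncated ORFs reported without a
terminating stop). It is *not* a coding-potential model: absolute protein
counts differ from Prodigal-style callers, but the monotone response to ε
does not depend on the caller.

The closed form (`expected_mean_orf`) for the expected mean called ORF
length is

    E[L] = 1 / (1/L0 + q),     q = 1 − (1 − c·ε)^3,

where `L0` is the true mean protein length (codons), `q` the per-codon
truncation probability, and `c` the probability that a single-base error
truncates the reading frame. `c` is computed exactly from the genetic
code: of the 549 single-base substitutions of the 61 sense codons, 23
create a stop (c_sub = 23/549 ≈ 0.042), while insertions and deletions
always truncate (a frameshift ends the readable frame); the
substitution:insertion:deletion mix weights these. Adding the rates 1/L0
and q is exact only for a memoryless gene-length law, which is why the
generator draws gene lengths geometrically (below).

The calibration experiments inject substitution-only errors. This
isolates the stop-codon mechanism; under an indel-dominated mix the
truncation coefficient rises to c ≈ 0.68 and the proteins/Mb curve peaks
near ε ≈ 0.016 and then falls, because most called fragments drop under
the 30-aa floor — the regime raw (uncorrected) long reads occupy, which
is why raw read sets can show *fewer* proteins/Mb than corrected ones.
The calibration also measures mean ORF length anchored at true gene
starts (valid because substitutions preserve coordinates), restricted to
starts with 3.6 kb of read remaining so right-censoring is negligible.

## The synthetic community generator

The generator is the ground truth that makes every downstream stage
scorable. Each genome is tiled with non-overlapping forward-strand genes
(geometric amino-acid length, default mean 250 aa — between the mean
protein sizes of the two reference organisms the study conditions cite)
separated by 50-bp intergenic gaps. Two fixed "stop kernel" constants
keep six-frame calling clean so the planted protein-length distribution
is exactly what the caller can recover:

* inside genes, every 24th–29th codon is a fixed 6-codon sense cassette
  that contains stop triplets in both shifted forward frames and
  reverse-complement stop triplets (TTA/CTA/TCA) at all three offsets, so
  every non-coding frame hits a stop at least every 24 codons (< 30 aa,
  the caller floor);
* each intergenic gap is flanked on both ends by a 15-bp wall
  (`TAATTAATTAATTAA`) with stops in all six frames at any placement; the
  wall abuts the gene directly, which also pins the called ORF start to
  the planted ATG (in the gene's own frame the wall reads `…TAA` just
  before it).

Both constants were found by exhaustive search over sense-codon strings;
a unit test re-verifies their defining property. Codon usage is GC-biased
to hit `gc_target` ± 0.02 — the base-level bias is solved numerically
(Brent) after counting the fixed kernel content — with a per-genome
Dirichlet jitter over sense codons giving each genome a distinct
tetranucleotide signature even at equal GC. Reachable GC is roughly
0.25–0.72 because the kernels are AT-rich.

Reads: long-read lengths are lognormal, parameterised by the target mean
(default 5,400 bp, σ = 0.4, truncated to [500 bp, 50 kb]); source genomes
are drawn ∝ abundance × length; abundances are lognormal (σ = 1). The
per-pass error table {5: 1%, 10: 0.1%, 15: 0.05%} encodes the
conventional CCS pass→accuracy mapping; the sub:ins:del mix defaults to
1:1:1. Start positions are drawn so reads fit inside the genome;
truncation applies only when a drawn length exceeds the genome. Short
reads are fixed-length 2×100 bp pairs with substitution-only errors.
Planted features: unique 600-bp single-copy marker genes spread evenly;
GT clusters (6 consecutive genes labelled family "GT", E = 1e-50); CRISPR
arrays (near-identical repeats, each copy carrying at most one planted
mutation, spacers copied verbatim from the emitted virome with recorded
provenance); rhodopsin genes derived from a shared per-community template
with 2% codon divergence; optional rRNA-ITS operons from shared
templates.

What the generator does **not** emulate: real genomes are not wall-to-wall
single-strand coding with a stop kernel; real communities have strain
microdiversity, conserved inter-genome homology, chimeras and uneven
within-genome coverage; CCS error is indel-dominated and
context-dependent; 16S extraction and functional annotation are replaced
by truth-derived tables. Passing tests therefore demonstrate correctness
of the *computations* under known structure, not end-to-end performance
on environmental data.

## Consensus taxonomy and profiles

A contig or read is classified at a rank when ≥ 50% of **all** its genes
(no-hit genes count in the denominator) share the same best-hit taxon;
sequences under 5 kb are unclassified; CRISPR-bearing sequences use 0.7.
Boundaries are implemented as ≥ with the threshold configurable, since
the source procedures mix "at least 50%", ">50%" and ">70%" phrasings; a
tie at the top is conservatively unclassified. 16S fragments are kept
when identity ≥ 80% and alignment length ≥ 90 bp. Profiles include an
"unclassified" row and sum to 1; a display cutoff can pool rare taxa.

## Binning, marker tally, RPKG, ANI

RPKG (reads per kb of contig per Gb of metagenome) counts each read at
most once — its best alignment by identity, then length, then
lexicographic contig id — under the recruitment rule identity ≥ 99% and
alignment strictly > 50 bp.

Binning stratifies contigs by phylum-level call (unclassified pooled),
then clusters within each stratum on [first 3 PCA scores of the 136
canonical tetranucleotide frequencies, GC, log10(RPKG + 0.01) per
sample], all columns standardised. The pseudo-count tames the
orders-of-magnitude coverage range. Clustering is agglomerative (average
linkage, Euclidean) — deterministic, no density parameter. The cluster
count is chosen by silhouette with two refinements that experience with
the scenario forced: exact-duplicate feature rows are collapsed first
(duplicates carry no structure but drive the silhouette of fine splits
toward 1), and among candidate k the smallest within 0.05 of the best
silhouette wins, so finer splits must earn a clearly better score. If no
split reaches silhouette 0.40 the stratum stays one bin; 0.40 sits above
the noise floor observed for splits of composition vectors drawn from a
single homogeneous genome (≈ 0.17–0.35 for 6–20 kb contigs) and well
below the scores of genuine multi-genome structure (≥ 0.6).

Bin quality is a simplified single-copy **marker tally**, not a
lineage-aware estimator: completeness = 100 × distinct markers present /
markers expected; contamination = 100 × (observations − distinct) /
expected; medium quality requires completeness > 50 **and**
contamination < 5, both strict; high additionally requires completeness
> 90. Absolute values are comparable only within this package.

ANI follows the ANIb fragment convention (1,020-bp non-overlapping query
fragments, trailing remainder dropped; contributing fragments need ≥ 30%
identity over ≥ 70% of their length; ANI = mean identity of contributing
fragments). Fragments are aligned with edlib in semi-global (infix) mode
on whichever reference strand shares ≥ 2 exact 16-mers with the
fragment; identity = 1 − edit distance / fragment length. The seed
requirement replaces the local-alignment behaviour of BLAST-based ANIb:
a semi-global alignment of unrelated DNA reports ≈ 50% identity, so
without seeding the 30%/70% rule would never reject. The practical floor
is ANI ≈ 75–80% — below that fragments stop seeding — which matches the
range where fragment ANI is considered meaningful anyway. Self-ANI is
exactly 100 regardless of fragmentation.

## Feature mining

**GT islands.** A window of ≤ 20 consecutive genes holding ≥ 5 GT genes
with E < 1e-40 on a parent ≥ 5 kb qualifies; overlapping qualifying
windows merge, and islands are reported trimmed to their first and last
GT gene. The implementation enumerates minimal 5-GT cores and merges
their window-expanded intervals, which is provably equivalent to merging
all qualifying windows (every qualifying window contains a core); a
brute-force all-windows oracle verifies this on random tables.

**CRISPR arrays.** A minimal detector, not a CRISPRdetect/CRISPRCasFinder
replacement: exact 13-mers recurring at an array-compatible distance
seed candidates; the maximal exact match around the seed pair is chained
across the sequence by Hamming search (repeats 21–48 bp, spacers
20–72 bp, ≥ 3 copies, each copy ≥ 90% identical to the column-majority
consensus). Repeat boundaries are the maximum-scoring contiguous column
interval overlapping the seed, each column scoring its cross-copy
majority support minus a threshold just under the copy number (n − 0.75
for ≥ 5 copies, n − 0.25 below, where a mutated column cannot be
distinguished from chance). A boundary column whose support ties chance
spacer agreement is intrinsically ambiguous, so boundaries on mutated
arrays can be off by one. Rejected candidate chains are memoised so the
periodic coding cassette of the synthetic genomes (or any genomic
microsatellite) costs one evaluation instead of thousands. The evidence
score is simply the repeat count; cutoffs quoted on other detectors'
evidence scales do not transfer.

**Spacer matching.** Exact full-length Hamming comparison of each spacer
at every target offset on both strands — no heuristic seeding; accepted
iff identity > 97% with 100% of the spacer aligned, so a 30-bp spacer
tolerates no mismatch and a 40-bp spacer exactly one. A sliding oracle
verifies the implementation.

**Protein clustering.** Greedy incremental clustering, cd-hit style:
sequences longest-first, each joining the first representative at ≥ the
level's identity, hierarchical from 100% down to 30% in 10% steps, after
a strict > 200 aa length filter. Identity is matches / alignment columns
of a unit-gap-cost global alignment (Biopython PairwiseAligner); exact
alignment identity differs slightly from cd-hit's heuristic word
identity, so counts near a threshold may differ from cd-hit's.

## Scenario sizes and determinism

Every stochastic step takes an explicit seed and is reproducible
byte-for-byte; experiment seeds are derived from one master seed via
`numpy` SeedSequence spawning. The standard scenarios — three 150-kb
genomes for read QC (~800–1,200 reads of mean 5.4 kb per condition, ~4–6
Mb), sixty 20-kb contigs for binning, 60-kb references for ANI, 120-kb
genomes for feature recovery — were sized to hold the relevant sampling
errors to a few percent (e.g. ~5,000 called ORFs per QC condition gives
a standard error near 3 aa on the mean protein size) while a full
pipeline pass stays interactive.

## Known limitations

* The ORF caller reports every six-frame ORF; on real (kernel-free)
  genomes it over-calls antisense and nested ORFs, so only error-response
  trends, not absolute counts, transfer.
* The marker tally ignores lineage-specific marker sets; completeness is
  meaningful relative to the planted universe only.
* The CRISPR detector requires ≥ 3 repeats with in-range spacers and has
  the boundary ambiguity noted above; arrays whose repeats diverge > 10%
  from the consensus are missed by design.
* Fragment ANI is undefined (flagged, not 0) when no fragment aligns;
  values below ~80% are outside the method's sensitive range.
* The greedy clusterer's results depend on the longest-first order at
  exact ties; ties are broken lexicographically by id for determinism.
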