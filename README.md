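# lrmine

Long-read metagenome mining: the bespoke computations of a PacBio
CCS/HiFi versus Illumina marine-metagenomics workflow, re-implemented as
a tested, reusable Python pipeline and exercised end-to-end on a
ground-truthed synthetic community.

It is aimed at microbial ecologists and bioinformaticians who want the
analysis layer that usually lives in one-off scripts — read-quality
proxies, consensus taxonomy, coverage normalisation, manual-style
binning, ANI, flexible-genome feature scans — as importable, seeded,
oracle-tested functions.

## What it computes

* **ORF-length read QC** (`orf_stats`). CCS reads ship without phred
  scores; per-base errors inject stop codons and frameshifts, so read
  accuracy is visible as a drop in mean called protein size and a rise in
  proteins/Mb. A six-frame stop-to-stop caller provides the statistics,
  and a closed form predicts the mean called ORF length:
  `E[L] = 1/(1/L0 + q)` with `q = 1 − (1 − c·ε)^3`, where `c` is derived
  exactly from the genetic code (23 of the 549 single-base substitutions
  of sense codons create a stop; indels always truncate).
* **Consensus taxonomy** (`taxonomy`): a contig/read is classified at a
  rank when ≥ 50% of all its genes share the same best-hit taxon (0.7 for
  CRISPR-bearing sequences; < 5 kb unclassified), plus 16S fragment
  filtering (identity ≥ 80%, alignment ≥ 90 bp) and rank-level profiles.
* **Binning and coverage** (`binning`): RPKG = recruited reads /
  (contig kb) / (metagenome Gb) with best-alignment-per-read and the
  99%-identity/>50-bp rule; taxonomy-stratified agglomerative clustering
  on [PCA of 136 canonical tetranucleotide frequencies, GC, log RPKG];
  single-copy marker tally with the medium-quality MAG rule
  (completeness > 50, contamination < 5, both strict); ANIb-style
  fragment ANI (1,020-bp fragments, 30% identity over 70% length).
* **Flexible-genome features** (`feature_mining`): glycosyltransferase
  islands (≥ 5 GTs, E < 1e-40, within 20 consecutive genes on ≥ 5-kb
  fragments), a minimal CRISPR repeat-chain detector, spacer-protospacer
  matching (> 97% identity over 100% of the spacer, both strands),
  cd-hit-style hierarchical protein clustering (100% → 30% identity), and
  per-Gb rates.
* **Ground truth** (`synthetic_community`): a generator for genomes with
  controlled GC and codon structure, lognormal abundances and read
  lengths, the CCS pass→accuracy error model (5/10/15 passes → 99 /
  99.9 / 99.95%), and planted markers, GT clusters, CRISPR arrays (with a
  matching virome) and rhodopsins — every read with provenance, so each
  stage is scored against truth. See `docs/methods.md`.

## Worked example

The numbered drivers under `analysis/` run the pipeline on the synthetic
community and write tables under `results/`. The read-quality sweep
(`python analysis/02_read_quality.py`) prints:

```
  eps  n_reads  n_proteins  mean_protein_aa  proteins_per_mb  total_bp
0.000      800        5230       254.963480      1195.613311   4374324
0.001      800        5528       238.145622      1277.375889   4327622
0.010      800        7816       169.994626      1793.540455   4357861
0.050      800       16239        81.673872      3763.250110   4315153

mean protein size strictly decreasing with error: True
proteins/Mb strictly increasing with error: True
closed-form check at eps=0.01: simulated 187.1 aa vs expected 190.2 aa (1.7% apart, n=2985)
```

Error-free reads recover the planted 250-aa mean protein; at 1% error
the mean called protein has collapsed to ~170 aa while the count per Mb
has inflated by half — the signature by which raw and pass-corrected
read sets are told apart. The simulated mean ORF length agrees with the
closed form within a few percent.

Binning and ANI (`python analysis/04_bin_mags.py`):

```
 bin_id  n_contigs  completeness  contamination quality
bin_001         20         100.0            0.0    high
bin_002         20         100.0            0.0    high
bin_003         20         100.0            0.0    high

adjusted Rand index vs planted genomes: 1.000 (3 bins over 60 contigs)
ANI self 100.00%, 5%-mutated reference 95.00%
```

Sixty 20-kb contigs from three genomes (GC 0.30/0.50/0.70, coverage
5/20/80) are recovered perfectly, each bin holding all 40 of its
genome's markers; fragment ANI returns exactly 100 on self and 95 on a
5%-substituted reference. Feature mining
(`python analysis/05_mine_features.py`) finds all planted GT islands and
CRISPR arrays and matches every detected spacer to the virome:

```
3 GT islands (7907/Gb of genome sequence)
3 CRISPR arrays, 12 spacers, 12 matched to the virome
3 rhodopsins (7907/Gb); cluster counts by level: 100%:3, 90%:1, 80%:1, ...
```

There is also a CLI for the individual stages:

```sh
lrmine stats contigs.fasta
lrmine simulate --config community.yaml --seed 7 --outdir sim/
lrmine orfqc reads.fastq --min-read-bp 1000
lrmine classify --genes genes.tsv --contigs contigs.fasta
lrmine bin --contigs contigs.fasta --alignments aln.tsv --metagenome-gb 20
lrmine ani --query bin.fasta --ref reference.fasta
lrmine gt-scan --genes genes.tsv
lrmine crispr contigs.fasta
lrmine cluster --proteins rhodopsins.faa --levels 100:30:10 --min-len 200
```

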