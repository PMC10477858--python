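# Methods

## Scope and model

`phameth` treats a phage community's DNA methylome as a set of called
modified bases (m6A or m4C, strand-specific, with coverage and IPD-ratio
metadata) on assembled phage genomes, together with the MTase gene content
of the phages and of a reference set of bacteria. The analyses it
implements are deliberately rule-based and statistical rather than
model-fitted: an ensemble vote for viral recognition, density ratios for
methylation, subsumption algebra for degenerate motifs, Markov clustering
for protein families, and a two-witness homology rule for host
assignment.

## Coordinate and counting conventions

* Coordinates are 0-based half-open in memory; GFF3 on disk is 1-based
  inclusive. The converters in `phameth.io` are the only place the
  translation happens.
* A methylation site is keyed by (genome, position, strand, type); calls
  repeated across samples collapse to one site.
* Density denominators count target bases on **both** strands from the
  forward sequence: for m6A the forward A count plus the forward T count
  (a forward T is a reverse-strand A), for m4C forward C plus forward G.
  Base-modification calls are strand-specific, so the denominator must be
  too; with this convention the genome-wide density is exactly the
  target-base-weighted mean of the coding and non-coding densities.
* The per-CDS modified-base ratio uses the CDS length as denominator by
  default; `cds_summary(..., per_genome_length=L)` switches to the whole
  genome length for the literal reading of a per-genome-length figure.
* Sequencing depth, used as the control variable of the partial
  correlation, is the summed coverage of a genome's sites across samples
  (an accumulated-coverage proxy; no per-read data are modelled).

## Rule thresholds

The classifier comparators are intentionally asymmetric and are encoded
exactly as stated by their sources: VirSorter ≥ 0.7 but VirFinder > 0.6
and PPR-Meta > 0.7; the phage-orthologous-group criterion needs ≥ 3 ORF
hits *and* ≥ 2 hits per 10 kb with real-valued length normalisation;
the CheckV rescue route needs ≥ 90% completeness plus one criterion.
Lifestyle bins over the virulence score are [0, 0.3] / (0.3, 0.5] /
(0.5, 0.7] / (0.7, 1], so a score of exactly 0.5 is uncertain-temperate.
Host assignment requires SimScore strictly above 90 from at least two
distinct phage proteins whose *best* hits agree on the same host; missing
tool scores fail their criterion rather than raising.

## Motif algebra

A motif pattern P "overlaps" Q when some window of the longer pattern is
position-wise contained (IUPAC set ⊆) in the shorter, more degenerate
pattern; at equal length either containment direction counts, so the
predicate is symmetric in its arguments. Dereplication removes, for each
overlapping same-type pair, the more specific pattern (the longer one, or
at equal length the position-wise contained one; exact equivalence keeps
the lexicographically smaller), iterated to a fixed point — the output is
a subset of the input and idempotent. Reverse-complement checking is
available behind a flag and off by default. Support filtering counts
distinct genomes with at least one occurrence (default threshold 100
genomes, lowered to the community size in small synthetic runs).

## Statistics

* Partial Pearson correlation uses the closed form
  r = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) with a two-sided p-value
  from t = r·√((n−3)/(1−r²)) on n−3 df; it equals the Pearson correlation
  of the OLS residuals on the control, which `residualize` computes for
  plotting. A constant control reduces to the plain correlation; exact
  collinearity raises.
* Non-orphan enrichment reports the one-sided hypergeometric upper tail
  P(X ≥ k) for drawing n from the (N, K) population as passed by the
  caller (the population's composition — with or without the sample — is
  the caller's choice and is not asserted), and a chi-square without
  continuity correction on [[k, n−k], [K, N−K]].
* ROC AUC is the Mann–Whitney statistic with ties counted 1/2.

## Markov clustering

No installed package provides MCL, so it is implemented directly:
self-loops weighted by each node's maximum incident edge weight, column
normalisation, then alternating expansion (matrix squaring) and inflation
(entrywise power 2.0 with column renormalisation), pruning entries below
1e-5, until the largest entry change falls below 1e-8 (cap 100
iterations, warning on non-convergence). Clusters are read off attractor
rows (non-negligible diagonal); overlapping attractor supports merge, and
unreached nodes become singletons, so the result always partitions the
node set and never crosses connected components. Edge weight is the
SimScore; input edges are kept when query coverage is strictly above 75%
and e ≤ 1e-5, symmetrised by the larger SimScore.

## Protein similarity

`align_proteins` performs local alignment with BLOSUM62 and affine gaps
(open 11, extend 1), reporting percent identity over alignment columns
and query coverage over the query length; empirical significance against
a residue-shuffled null is available separately. Precomputed similarity
tables are accepted everywhere an alignment would be, so any external
aligner can be swapped in. Inside the synthetic community, proteins are
evolved by point substitution only and share a common length, so the
generator's own edge tables use exact positional identity with 100%
coverage — a deliberate choice that makes planted identities exactly
controllable.

## The synthetic community generator

The generator emulates the statistical structure of the study inputs, not
their biology:

* Genomes are i.i.d. nucleotides at a target GC (default 0.45, lengths
  8–20 kb); CDS intervals (150–450 bp, ≈10 per 10 kb) are placed without
  overlap with uniform random gaps and carry functional-category labels.
* Methylation is planted **only** at the methylated base of occurrences
  of the configured motifs (defaults: GATC and GANTC for m6A, CCWGG and
  GCGC for m4C), sampled to per-lifestyle, per-type target densities.
  Defaults make m4C density rise and m6A fall with virulence
  (0.004→0.010 and 0.012→0.006 across the four lifestyle bins), values
  chosen to sit well below what the motif set supports on a random
  genome so targets are reachable; an unreachable target warns and emits
  every candidate.
* Lifestyle labels are drawn from the observed composition of a
  high-quality gut-phage collection (13.68 / 59.58 / 18.61 / 8.11%), and
  the virulence score is uniform within the label's bin.
* Host links: 80% of phages are linked by default; each linked phage
  carries two proteins evolved from its host's MTases at 95% identity,
  and a different decoy bacterium receives copies of the same parents at
  70% — the regime in which two-witness assignment is expected to be
  near-perfect, which is what the recovery tests check.
* Abundance: presence probability follows a logit link,
  logit(p) = logit(0.3) + 3·c·z, where z is the standardised planted
  density and c the prevalence–density coupling (default 0.8; c = 0
  decouples them). Present genomes draw an RPKM of 0.6 + LogNormal(0.5,
  0.8), absent ones Uniform(0, 0.3); counts are rounded from RPKM and
  the emitted RPKM matrix is recomputed exactly from the counts.
  Site coverage is Poisson(20), so depth correlates with site count.
* Recognition evidence gives planted virals ≥ 2 passing criteria with
  probability 0.9 (otherwise one criterion with high CheckV
  completeness); non-virals get sub-threshold scores and occasionally a
  bacterial contamination hit.
* Taxonomy is a rank-complete species→genus→family tree (defaults
  30/15/8) with every genus and family guaranteed non-empty.

All randomness flows through one `numpy` generator seeded from the
config, so identical config + seed reproduce byte-identical artifacts.

What passing these tests does **not** show: the generator has no genome
architecture, codon structure, read-level noise, partial methylation,
alignment error or incomplete reference effects, so recovery rates here
are upper bounds on real-data performance. In particular the
near-perfect host-prediction precision on planted 95%-identity links
says nothing about precision on natural communities, where identity
distributions are continuous and reference genomes are missing.

## Problem sizes

The default community is 50 phages × 50 bacteria × 50 samples; the
recovery analyses sweep ten seeds of it, and the acceptance script uses
the same sizes. These are the scales at which every statistic stabilises
while a full ten-seed sweep stays under a minute on one CPU.

## Known limitations

* m5C is out of scope (not reliably callable by the upstream technology).
* De novo motif discovery is out of scope; the toolkit consumes motif
  lists and implements only dereplication, overlap and scanning.
* The hypergeometric population convention is caller-defined; see the
  statistics section.
* MCL is dense (numpy); adequate for the ≤ few-thousand-protein
  communities generated here, not for reference-scale catalogues.
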