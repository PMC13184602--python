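# Methods

## Scope and data model

`methkit` operates downstream of bisulfite alignment and methylation
extraction. Its input unit is the per-cytosine report row
(chromosome, 1-based position, strand, methylated count, unmethylated count,
context, trinucleotide); its analysis units are classified cytosine sites,
per-gene exonic aggregates, and per-contrast delta tables. External formats
are 1-based inclusive (reports, GFF3); all internal interval arithmetic is
0-based half-open, converted only at the I/O boundary. Site positions remain
1-based throughout because they are point coordinates.

## Site classification

A site passes filtering when its total depth `m + u` is at least `min_depth`
(default 5, boundary inclusive). The phrase "coverage on both DNA strands"
is ambiguous for asymmetric contexts: CHH sites have no strand-symmetric
partner, so a universal both-strand rule cannot exist. The default is
therefore plain per-site depth, with `require_both_strands` as an opt-in
that additionally requires the symmetric partner of a CpG (±1 bp, opposite
strand) or CHG (±2 bp) site to pass the same cutoff.

Context is determined from the reference on the site's own strand: with b₁
and b₂ the next two downstream bases, `b₁ = G` gives CpG, else `b₂ = G`
gives CHG, else CHH. A trinucleotide that runs off the contig or contains an
N is undeterminable; such sites are excluded from all statistics and logged.

Region assignment ignores gene strand (methylation on either strand within
an exon is exonic) and uses exon > intron > intergenic precedence when
annotations overlap, with ties between genes broken by (start, gene id) for
determinism. The assignment is implemented as vectorised interval joins
(pyranges); tests check it against a per-base brute-force scan.

Intensity categories: level ≤ 30 % hypomethylated, ≥ 70 % hypermethylated,
strictly between intermediate. Both boundaries are inclusive toward their
extreme category.

A *methylated site* is a depth-passing site with ≥ 1 methylated read
(optionally also a minimum level). This choice keeps the hypomethylated bin
populable — any definition based on a high level threshold would empty it —
and makes the three composition triples (context, intensity, region) sum to
100 % over a common denominator. Summaries also report the
methylated-of-all-sites fraction so both denominators are available.

## Gene-level aggregation

The gene-level statistic is the read-weighted exonic level
`100 · Σm / Σ(m+u)` rather than the unweighted mean of site levels: it is
robust to depth heterogeneity across sites and invariant to splitting a
site's reads across rows (conservation of read mass). The unweighted mean is
available via `weighted=False` for sensitivity analysis. A gene is
*methylated* in a sample when at least one exonic site is methylated. Genes
whose exons overlap another gene's exons double-count the shared sites in
both records, keeping each record self-contained. Hypermethylated exonic
position counts per chromosome × context (level ≥ 70 %) are emitted as the
observational units for the ANOVA layer.

## Contrast statistics

Deltas are computed over the union-methylated, both-covered gene universe;
genes covered in only one condition are dropped with a logged count. The
effect size is the sample median (mean of the central pair for even n) and
the across-loci SD uses the n−1 denominator. Two variability notions exist
in this kind of study — across loci within a contrast, and across stages of
methylated-gene counts — and both are computed and labelled distinctly
(`sd_loci` vs `variability_across_stages`).

The Wilcoxon signed-rank test drops zero deltas before ranking (the
classical treatment; Pratt's method is switchable), uses the exact null
distribution for n ≤ 25 without ties, and the normal approximation with
continuity correction and midrank ties otherwise. An all-zero delta vector
is degenerate: p = 1 with a flag rather than an error. BH adjustment spans
exactly the family of contrasts passed in one call (e.g. all stages against
the mother-plant baseline).

DMG calling uses |Δ| ≥ threshold with a default of 10 points; a gene with
Δ = 0 is never a DMG, so a zero threshold selects exactly the genes with any
shift. Because a fixed count is hard to compare across genotypes with
different dynamic ranges, the count is also reported normalised per 100
points of observed |Δ| range; this normalisation is one defensible reading
of a "per 100-point difference" comparison and is flagged as such, not
asserted as the only one. Percent change of methylated-gene counts is
`100·(test − ref)/ref` with the sign retained and two decimals reported;
no silent rounding.

ANOVA is one-way over condition × context groups with chromosomes as
replicates; groups with fewer than two observations are excluded with a
warning. F and p are computed from explicit sums of squares so the
degenerate zero-residual-variance case is well defined: distinct means give
F = ∞, p = 0 and the letter display proceeds; identical constant groups give
F = 0, p = 1. Fisher's LSD uses the pooled mean-square error on the residual
degrees of freedom, protected by the ANOVA (pairs are declared different
only when the ANOVA itself is significant). The compact letter display
assigns one letter per maximal clique of the non-significance graph
(exhaustively for ≤ 16 groups, greedily above), which guarantees that groups
sharing a letter never differ at the chosen level and that non-different
pairs share at least one letter.

## Pattern layer

The methylation matrix is gene × sample levels restricted to complete cases
(no imputation). Variance ranking uses the n−1 denominator with ties broken
by feature identifier. PCA runs on centred, unscaled levels — all features
share the percent unit — with scaling as a flag; samples are the
observations. Clustering of commonly hypermethylated genes (gene level
≥ 70 % in *every* sample) defaults to Euclidean distance with average
linkage; the dendrogram is exported as Newick in the ultrametric convention
(a node sits at half its merge height, so leaf-to-leaf path length equals
the cophenetic distance). Overlap reports give the full
inclusion–exclusion decomposition for 2–3 sets and per-pair/per-triple
reports beyond that.

## Synthetic data generator

The generator emulates the post-extraction statistical structure of a plant
WGBS study; it does not simulate reads, bisulfite conversion error, or
alignment.

* **Genome layout.** Uniform A/C/G/T sequence (an option injects Ns to
  exercise boundary handling) split into `chr1..chrN`; genes are placed
  non-overlapping with ≥ 1 bp intergenic gaps drawn from a random
  composition. Defaults (100 kb, 40 genes of 200–600 bp, exon fraction 0.4
  of gene length, 1–4 exons) give roughly 84 % intergenic / 10 % exonic /
  6 % intronic cytosines, the canonical plant layout in which most of the
  genome is intergenic and exons are a small minority.
* **Methylation.** Site probabilities are beta-distributed around
  context-specific means — CpG 0.80, CHG 0.50, CHH 0.10, the typical plant
  gene-body pattern of high CpG, intermediate CHG and low CHH methylation —
  with concentration 10 (mean·10 and (1−mean)·10 as beta parameters), so
  site-to-site variation is substantial without being bimodal. Degenerate
  means of exactly 0 or 1 bypass the beta draw.
* **Depth.** Negative-binomial with mean 10 and dispersion 5 by default,
  placing realistic mass on both sides of the ≥ 5 depth filter.
* **Treatment.** Baseline probabilities are drawn once from the config seed,
  independent of condition; a condition's effect (in percentage points /
  100) is added to exonic sites of the affected gene fraction and clamped to
  [0, 1]. Sharing the baseline makes the treated-minus-control probability
  difference exact by construction in the truth table, so effect-recovery
  tests measure only sampling noise, not baseline re-draws.
* **Study design.** One pooled report per condition by default (matching
  designs that pool biological replicates before sequencing);
  `n_samples_per_condition` switches to replicated output, with independent
  count draws per replicate from a (seed, condition, replicate) stream.

What the simulator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: linkage disequilibrium of methylation
along the genome (sites are independent), M-bias and conversion error,
transposable-element and repeat structure, chromosome-scale methylation
gradients, and biological covariance between genes. Results on simulated
data validate the computational chain, not biological effect sizes.

## Problem sizes and numerical choices

Tests run on 40–100 kb genomes (25–60 genes); effect-size recovery uses a
700 kb / 500-gene / depth-20 study, and null calibration draws 1,000
replicate contrasts on a fixed 80 kb / 60-gene genome, redrawing only read
counts per replicate (annotation depends solely on positions, so it is
computed once). The acceptance script uses 400 kb / 300 genes / depth 20.
These sizes were chosen so the full suite runs comfortably on a laptop while
leaving effect estimates' sampling error well inside the asserted
tolerances (±0.5 points for median-shift recovery; a 99 % binomial interval
around the nominal 5 % rejection rate).

Floating-point outputs are written at fixed precision (4 decimals for
levels, 2 for percentages in summary tables); percentage triples are
asserted to sum to 100 within 0.01. Determinism everywhere derives from
`numpy.random.default_rng` seeded with structured keys
(config seed, stream id, condition, replicate), so adding a condition or
replicate never perturbs other streams.

## Known limitations

* Region annotation attributes a site in overlapping exons of two genes to
  one gene (deterministic tie-break) for the site table, while gene
  aggregation counts it in both genes; the two views answer different
  questions and are documented rather than reconciled.
* The per-100-points DMG normalisation divides by the observed |Δ| range,
  which is sample-size dependent; comparisons across very different gene
  universes should prefer the raw count plus threshold.
* The Wilcoxon test assumes exchangeability of paired levels under the
  null; strong depth imbalance between conditions can violate symmetry.
* Promoter/flank and transposable-element aggregation, DMR (site-window)
  calling, and covariate-adjusted models are out of scope.
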