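# Methods

This note documents the models, defaults and numerical choices behind
`vernalnc`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinates and annotation model

All coordinates are 1-based and fully closed (the GTF convention); the BED6
export converts to 0-based half-open at the output boundary only. A
transcript is an ordered tuple of non-overlapping exons on one sequence and
strand; its *length* is the mature (spliced) length, the sum of exon
lengths, which is the quantity the 200-nt lncRNA rule applies to. Introns
are the maximal gaps between consecutive exons, so exons and introns
partition the transcript span exactly. Genes are groups of transcripts
sharing a sequence and strand; the gene *span* is the union extent of its
transcripts. Three per-chromosome interval indexes (exons, introns, spans)
back all overlap queries; every indexed query is tested against an
exhaustive all-pairs scan in the suite.

Transcripts spanning multiple sequences are rejected as malformed.
Strandless transcripts cannot be classified — antisense status is undefined
without a strand — and are reported as excluded with reason `unstranded`.

## Classification

Class codes are recomputed from geometry rather than parsed from an
assembler's output, so the pipeline has no external tool dependency; a
loader for precomputed class-code tables exists as an alternative entry
point. The decision order is: `match` (identical ordered exon boundaries to
a same-strand reference transcript), else `x` (≥ 1 bp merged exonic overlap
with reference exons on the opposite strand, and *no* same-strand exonic
overlap — same-strand exonic overlap preempts the antisense call), else `i`
(span contained in a single intron of some reference transcript, either
strand, with the strand relation recorded), else `u` (zero overlap with any
gene span on either strand — strict intergenicity), else `other`. The host
gene is the one with the largest merged exonic overlap, ties broken by
lexicographically smallest gene id, making outputs deterministic.

Categories follow the code, the length rule and the protein-homology
evidence (per transcript, the minimum e-value across hits): `u` splits into
putative mRNA (best e-value ≤ 1e-10) versus lincRNA; `x`/`i`/`u`-noncoding
transcripts shorter than 200 nt are excluded as `short`. The e-value
threshold and minimum length are configurable (`ClassificationConfig`);
hit semantics are the standard "significant iff e-value ≤ threshold", so
*lowering* the numeric threshold is the stringent direction and can only
move transcripts from putative mRNA to lincRNA.

Mono-exonic intergenic transcripts are retained (no mono-exon filter): the
classification is purely geometric and expression support is handled in the
expression stage, as a mean-FPKM floor (≥ 0.5 FPKM in at least one
condition) standing in for an upstream tool's internal "tested OK" status.

## Expression and differential calls

Expression arrives as a nonnegative FPKM matrix with two conditions (NV
reference, V alternative) inferred from sample-name prefixes. Fold change
is log2((V̄ + pc)/(N̄V + pc)) with pseudocount pc = 0.01 FPKM — small enough
to leave moderately expressed features untouched, large enough to keep
ratios finite at zero; the function is antisymmetric in its arguments by
construction.

The differential test is a deliberate stand-in for count-level machinery
that cannot operate on an FPKM matrix. The default is a moderated
two-sample t on log2(FPKM + pc): per-feature pooled variances s²_g (d_g =
n1 + n2 − 2 residual df) are modeled as s₀²·F(d_g, d₀) and the prior
(s₀², d₀) is fitted by matching the mean and variance of log s²_g to their
digamma/trigamma expressions (the classic squeeze-variance moment
estimator; the trigamma inverse is solved by Newton iteration). The
moderated statistic uses the posterior variance
(d₀ s₀² + d_g s²_g)/(d₀ + d_g) and d_g + d₀ df. Rationale: with two
replicates per condition a per-feature variance has 2 df, so even an
exactly specified pooled t misses ~2% of 16-fold effects on unlucky
variance draws, and Welch's form is far worse — its Satterthwaite df
collapse toward 1 and essentially nothing survives FDR control. Both plain
forms remain available (`DEConfig(moderate_variance=False[, equal_var=False])`).
Degenerate zero-residual-variance features get p = 1 when the group means
agree and p = 0 when they differ. With a single replicate per condition no
test is possible: p-values are absent, the direction falls back to the
high-fold-change rule and the result table is flagged.

BH q-values are computed by the package's own step-up implementation
(validated input in [0,1]; order-preserving; permutation-invariant) and are
cross-checked in the suite against an independent reference implementation.
A feature is `up`/`down` when supported, q < 0.05 and the fold change is
nonzero; "highly" regulated lists for enrichment additionally require
|log2 ratio| > 2. Category-level expression comparisons use per-feature
mean log2(FPKM + pc) and Tukey's HSD across categories with ≥ 2 features.

## Pairing and joint patterns

NATs pair with their antisense-overlap host, incRNAs with the gene owning
the containing intron (distance 0 by definition). lincRNAs pair with genes
whose span lies within 2 kb of the lincRNA span on the same sequence,
either strand; the gap is span-to-span, (later.start − earlier.end − 1),
with overlapping or abutting spans at distance 0. Span-to-span (rather than
TSS-based) measurement is an explicit assumption. The default policy pairs
*all* genes in the window ("the genes within 2 kb", plural); nearest-only
is available for sensitivity analysis. Pairs are lncRNA-centric: a gene may
appear in several records.

Joint patterns require an FDR-level call on *both* members: coordinate
(same non-ns direction), antagonistic (opposite), lnc_only / mrna_only /
neither. Pattern cells partition the pair set. Pair summaries report counts
per (category × lnc direction × mRNA direction) cell and per-category
Pearson and Spearman correlations of the two log2 ratios — both are
emitted because either convention is defensible for ratio data.

## Enrichment

The upper-tail hypergeometric probability P(X ≥ k) is accumulated in log
space (logsumexp over the pmf support) and matches exhaustive enumeration
to 1e-12 relative error for N ≤ 30. The background population defaults to
the expression-supported genes — the universe actually eligible for the
regulated lists — not the whole annotation; term gene sets are intersected
with the population before counting. Terms with k = 0 are not tested, which
keeps the BH burden to informative terms; results are sorted by
(fdr, p, term) and are independent of term iteration order.

## Synthetic data: what it emulates, and what it does not

The generator emulates the study design the pipeline targets: ~50
non-overlapping multi-exon genes on 3 chromosomes; 15 reference-matching
assembled transcripts; 40 planted lincRNAs (10 at planted proximal gaps in
(0, 2 kb]), 25 NATs, 10 incRNAs, 10 putative mRNAs and 2 sub-200-nt decoys;
a two-replicate NV/V FPKM matrix; a protein-hit table and a 30-term map
with one planted enriched term. Geometric margins guarantee unambiguous
class codes — NAT overlaps ≥ 50 bp inside a host exon, incRNAs ≥ 10 bp
inside an intron, intergenic gaps of 5–7 kb (more than twice the 2-kb
pairing window) — so planted-truth recovery can be asserted *exactly*.

Expression is log2-normal: FPKM = 2^(baseline + effect·[V] + noise), with
mRNA baselines N(5, 1.5²) and lncRNA baselines N(2, 1.5²) log2-FPKM
(lncRNAs expressed ~8-fold lower, as observed for plant lncRNA classes),
replicate noise sd 0.25 on the log2 scale (typical bulk RNA-seq replicate
variability), effect sizes drawn from {1, 2, 4} log2 units with random sign
at rate 0.35 per eligible feature. Pair-pattern quotas (6 coordinate, 2
antagonistic, 2 lnc-only, 2 mRNA-only NAT pairs; 2 coordinate incRNA pairs)
are planted with |effect| = 4 on the appropriate members, and all *other*
NATs, incRNAs and their hosts stay null so the planted NAT/incRNA pattern
counts are exact. Everything is byte-identical under a fixed seed.

What passing tests on this generator do **not** show: the generator has no
sequences, no read-level sampling noise, no length/GC biases, no dispersion
trends with expression level, no overlapping or nested genes, and no
correlation structure beyond the planted pair effects — so exact recovery
here demonstrates correctness of the geometry and statistics, not
performance on the messiness of real assemblies (fragmented transcripts,
ambiguous strand assignment, isoform-level class-code conflicts).

## Problem sizes used in checks

The acceptance script runs the published pair table (20 pairs, 40 fold
changes), the default synthetic dataset (50 genes, 102 assembled
transcripts), 1,000 random interval queries against the brute-force oracle,
200 random hypergeometric instances with N ≤ 30, ~3,000 BH p-values, 1,000
null features for false-call calibration, 100 planted 16-fold effects
(replicate noise sd 0.1, the low-noise regime for the power check) and 500
correlated pairs. Everything completes in a few seconds.

## Known limitations

- Class codes are recomputed from geometry; subtle assembler-specific code
  semantics (e.g. fuzzy match codes) are not reproduced.
- The DE stand-in consumes FPKM, not counts; it supplies direction, fold
  change and FDR-level calls, and is not a substitute for count-level
  inference when counts are available.
- The incRNA strand convention records, but does not filter on, the
  sense/antisense relation to the host — the field's definitions vary.
- Enrichment performs no ontology-graph propagation; the term map is taken
  as given.
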