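# Methods

`bach1sig` implements a target-gene discovery pipeline for a
transcriptional repressor (BACH1 in lung adenocarcinoma is the motivating
system): integration of ChIP-Seq binding evidence with knockout RNA-Seq
differential expression, motif co-localisation scanning, and downstream
applications of the resulting perturbation signature. This note records
the model, its assumptions, the tunable parameters, and the design
decisions taken where the procedure was genuinely open.

## Integration model

The unit of inference is the gene. Binding evidence enters as ChIP peaks
carrying a per-peak log2 enrichment ratio between the regulator-proficient
and regulator-knockout condition; expression evidence enters as a
DESeq2-style results table (log2 fold change and adjusted p-value) from
the same knockout contrast. The pipeline does not call peaks or fit the
DE model — those are upstream tools' jobs — it consumes their outputs.

**Peak-to-gene assignment.** A peak is assigned to a gene when the gap
between the two intervals is at most `window_bp` (default 10 000 bp);
peaks inside the gene body have gap zero, and a gap of exactly
`window_bp` is assigned ("within 10 kb" reads as ≤). Assignment is
strand-agnostic — the window is symmetric around the gene — and one peak
may serve several genes. All coordinates are normalised to 0-based
half-open on read (BED native; GTF converted), so the gap between
half-open intervals is simply `other.start − this.end` when disjoint.
Implementation uses an interval tree per chromosome with the query
widened by 1 bp per side so that touching the window-extended gene
interval counts as assignment; a brute-force all-pairs oracle confirms
equivalence in the tests.

**Filters.** A gene survives iff (i) it has ≥ 1 assigned peak;
(ii) its gene-level binding value reaches `binding_cutoff` (default 0.7,
genes strictly below are excluded); (iii) it passes the DE rule —
`padj < 0.1` (strict) with replicates, `|shrunken log2FC| > 0.3` (strict)
without; and (iv) it matches the direction filter (default `both`; `up`
selects genes induced by the knockout, the orientation in which the
repressor's direct targets appear). Multiple assigned peaks are
aggregated by the **maximum** log2 ratio — the binding filter exists to
prioritise high-affinity sites, and the maximum is the aggregation
consistent with that reading; the peak count is reported alongside so a
caller can audit the choice. Records with missing `padj` cannot
contribute a −log10 term and are excluded (counted and logged) rather
than imputed.

**Combined Score.**

    score = w_b · log2_ratio + w_f · |log2FC| + w_p · min(−log10 padj, cap)

with default weights (0.5, 0.25, 0.25), so binding and expression
evidence each contribute half. `padj` values of exactly zero are floored
to 1e-300 on read and the −log10 term is capped at 300: without the cap a
single floored p-value would dominate every ranking. Ranking is by score
descending with a fully deterministic tie-break (binding desc, |log2FC|
desc, gene id asc), so identical inputs give byte-identical output.
Fold-change sign conventions are the caller's responsibility; the
`flip_log2fc` flag flips a table oriented control-vs-perturbed.

## Motif scanning

Position frequency matrices (JASPAR format) are converted to base-2
log-odds against an i.i.d. background — uniform by default, configurable
— with a pseudocount (default 0.1) distributed proportionally to the
background:

    p(b, j) = (count(b, j) + pc · bg(b)) / (colsum(j) + pc)
    lo(b, j) = log2(p(b, j) / bg(b))

The null distribution of the window score (sum of per-column log-odds) is
computed **exactly** by dynamic programming: scores are discretised to
integer multiples of a granularity (default 1e-3 bits, rounding to
nearest) and the four per-base probabilities are convolved column by
column, which is exact on the lattice. Windows are scored with the same
discretised matrix, so reported p-values are exact survival probabilities
P(S ≥ s) for the discretised scores — the behaviour FIMO's users expect.
Tests verify the DP against exhaustive enumeration of all 4^w windows for
widths up to 8.

Numerical choices: −∞ cells (zero count, zero pseudocount) are floored to
−100 bits before the DP so the lattice stays finite; the floor sits far
below any significant score. Minus-strand windows are scored with the
reverse-complement matrix against the forward sequence and share the
forward-model null (the background is assumed strand-symmetric); hits are
reported in forward 1-based inclusive coordinates with the motif-strand
matched sequence. Windows containing N are skipped. No multiple-testing
correction is applied — the significance rule is a raw p < 0.01, the
convention this analysis follows. Co-localisation pairs hits from two
scans on the same sequence whose intervals overlap or lie within
`max_gap_bp` (inclusive) of each other.

## Signature applications

The perturbation signature is the coordinated induction of HMOX1, ZNF469
and HTRA3 on depletion/inhibition of the repressor (the extended set adds
NRCAM and FTH1, which were pruned for specificity).

**Response calls.** A gene is induced iff log2FC ≥ log2(fold_cutoff)
(default 2-fold) and, when a padj cutoff is given, padj < cutoff. Genes
absent from a table are *not assayed*, not failures — some cell lines
simply do not express one signature gene — and the overall call is made
on the assayed subset.

**Compound screening.** The original mining of public compound profiles
was done by inspection; the package formalises it as an auditable rule.
All genes in a profile are ranked by log2FC descending (average ranks on
ties); the mean rank percentile of the signature genes,
mean(1 − (rank−1)/(N−1)), summarises concordance; a compound is a
*candidate* iff every signature gene found in the profile has
rank ≤ `top_fraction · N` (default 5%) and is induced past the fold/padj
cutoffs. The rule is invariant to row order and reproduces the
qualitative selection ("signature genes among the most upregulated") with
explicit thresholds.

**Basal correlation.** The per-line signature score is, by default, the
mean of per-gene z-scores across the panel (z-scoring prevents any one
gene's expression scale from dominating); `score_method="mean"` gives the
plain mean, which is the right choice when the regression slope must be
interpretable on the raw expression scale — the slope of a z-scored score
is shrunk by each gene's marginal SD. Pearson r, the least-squares
slope/intercept of score on regulator protein level, and the two-sided
p-value for r are reported; zero variance in either variable raises an
explicit undefined-correlation error rather than returning NaN.

**qPCR.** `ddct_fold_change` implements the comparative ΔΔCt method
(fold = 2^−ΔΔCt after housekeeping normalisation, HPRT1 on the bench).

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes, with ground truth, so every stage is testable without sequencing
data. Reference conditions (the defaults): 500 non-overlapping genes
(2–50 kb) on a 20 Mb chromosome; 5 true targets, each with one peak of
log2 ratio ≥ 2.0 placed within 5 kb of the gene start, log2FC ≈ 3.0 (SD
0.2) up in the knockout and padj = 1e-8; null genes carry a background
peak with probability 0.6, ratio ~ Normal(0, 0.3) — so some clear the 0.7
cutoff by chance and the binding filter is genuinely exercised — and null
DE statistics with padj uniform on (0.1, 1], which keeps the DE filter's
boundary behaviour unambiguous. The planted padj is tied to the planted
effect: with `true_log2fc = 0` targets draw null padj, so the effect-off
control yields zero recovery. Compound libraries: 50 profiles over 1 000
genes, 3 planted inhibitors whose signature-gene log2FC ~ Uniform(4, 6)
(far above the standard-normal null) with padj < 1e-4; null compounds
draw signature genes from the null, i.e. uniform ranks. Cell panels: 60
lines, regulator protein ~ N(0, 1), each signature gene =
baseline − 0.8 · regulator + shared factor (SD 0.3) + noise (SD 0.3); the
shared factor plants positive gene–gene co-expression on top of the
regulator effect. All randomness flows through one seeded NumPy
`Generator`, so outputs are bit-reproducible per seed.

What the generators do **not** emulate: read-level noise, peak-shape
artefacts, mappability and blacklist structure, correlated DE errors,
realistic genome sequence, and batch effects. Passing recovery tests
therefore demonstrates that the pipeline's logic is correct and its
thresholds act where stated — not that the thresholds are optimal for any
real dataset.

## Verification scale

The test-bench runs at deliberately small sizes chosen to probe each
property, and the package's reference checks use: boundary sweeps of ~20–200
points per parameter; exhaustive 4^w enumeration up to width 8 (65 536
windows); single-seed recovery runs at generator defaults; and 200
replicates for the slope-recovery and null-control distributions. The
published analysis's headline gene count (1 638 integrated genes) depends
on the study's deposited peak and DE tables and is reproducible only with
those supplementary files as inputs; it is not asserted by the test-bench.

## Known limitations

* Per-gene aggregation by maximum ignores additive effects of multiple
  peaks; callers needing a different aggregation can use
  `assign_peaks_to_genes` directly.
* Exact p-values are exact on the discretised lattice; coarser
  granularities trade accuracy for speed (at 1e-3 bits the error is far
  below any decision boundary used here).
* The concordance rule is a formalisation of a manual selection; its
  defaults (2-fold, padj 0.05, top 5%) are reasonable but not fitted.
* The basal-correlation model is a simple linear regression; lineage
  structure in real panels (confounding by tumour type) is not modelled.
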