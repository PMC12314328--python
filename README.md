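# bach1sig

Tools for defining and applying a transcription-factor perturbation
signature from integrated ChIP-Seq and RNA-Seq data. The motivating
system is the repressor **BACH1** in lung cancer cells: given BACH1
binding peaks (WT vs knockout ChIP-Seq) and a knockout differential-
expression table, the pipeline ranks candidate direct targets, checks
motif co-localisation of BACH1/NRF2-type binding sites, and applies the
resulting signature (HMOX1, ZNF469, HTRA3) downstream — screening
compound expression profiles for candidate BACH1 inhibitors, testing the
basal inverse correlation between BACH1 protein level and signature
expression across cell-line panels, and converting qPCR Ct values to fold
changes. It is aimed at computational biologists who have peak and DE
tables in hand and want the integration and signature logic to be
explicit, tested and reproducible.

## The model

A gene is a candidate direct target when it is both **bound** and
**regulated**. Peaks are assigned to a gene when they fall inside it or
within 10 kb of either end; genes whose strongest assigned peak has
log2(BACH1/BACH1-KO) ratio below 0.7 are excluded; genes must be
differentially expressed (padj < 0.1 with replicates, |shrunken
log2FC| > 0.3 without). Survivors are ranked by the Combined Score

```
score = 0.5 · log2Ratio + 0.25 · |log2FC| + 0.25 · −log10(padj)
```

so that binding and expression evidence contribute equally. Motif
scanning converts JASPAR count matrices to log-odds PWMs and computes
**exact** match p-values by dynamic programming over a discretised score
lattice (FIMO-style, threshold p < 0.01, both strands). A seeded
synthetic-data module generates annotations, peak/DE tables, compound
libraries and cell panels with planted ground truth, so every stage is
testable without sequencing data.

## Worked example

Simulate a knockout experiment (5 planted targets among 500 genes) and
rank candidate targets:

```
$ bach1sig simulate experiment --seed 1 --out demo
$ bach1sig integrate --genes demo/genes.bed --peaks demo/peaks.tsv \
      --de demo/de.tsv --direction up -o demo/ranked.tsv
5 genes retained -> demo/ranked.tsv
$ head -4 demo/ranked.tsv
gene_id  binding_value  n_peaks  log2fc             padj   combined_score      rank
G0319    2.27966        1        2.92745680951792   1e-08  3.87169420237948    1
G0270    2.2112         1        3.011664943957998  1e-08  3.8585162359894993  2
G0186    2.11662        2        2.989636155220755  1e-08  3.8057190388051887  3
```

Only five genes survive the binding + DE filters, and they are exactly
the five planted targets (`demo/truth.json`): each combines a strong peak
(log2 ratio ≈ 2, contributing ~1.0 to the score), ~8-fold induction in
the knockout (~0.75), and padj = 1e-8 (2.0). In the library:

```python
from bach1sig import SimulationConfig, simulate_cell_panel, basal_correlation
panel, truth = simulate_cell_panel(SimulationConfig(seed=11))
c = basal_correlation(panel, score_method="mean")
print(f"r = {c.pearson_r:.3f}, slope = {c.slope:.3f}, n = {c.n}")
# r = -0.888, slope = -0.662, n = 60
```

The panel plants signature expression = baseline − 0.8·(BACH1 protein) +
shared factor + noise across 60 lines; the fitted slope estimates the
planted −0.8 (here −0.66 at n = 60; over 200 replicate panels the
estimates centre on −0.8) and the strongly negative r reproduces the
expected repressor-vs-signature inverse correlation. Other subcommands:
`scan-motifs` (PWM scanning of FASTA regions), `score-compounds`
(signature concordance over per-compound DE tables), `correlate`, and
`run-all`, which chains every stage on synthetic inputs and writes a run
manifest.

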