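"""ChIP-Seq x RNA-Seq integration: rank candidate direct targets of a
transcriptional regulator.

The procedure assigns binding peaks to genes (any peak inside a gene body
or within ``window_bp`` — 10 kb by default — of either end), keeps genes
whose strongest assigned peak reaches the binding cutoff (log2 enrichment
ratio >= 0.7 by default) and that are differentially expressed
(padj < 0.1 with replicates, or |shrunken log2FC| > 0.3 without), and
scores each survivor with a weighted Combined Score

    score = 0.5 * log2_ratio + 0.25 * |log2FC| + 0.25 * -log10(padj)

so that binding evidence and expression evidence each contribute half.
Genes are ranked by descending score with a fully deterministic tie-break.

Multiple peaks assigned to one gene are aggregated by the *maximum*
log2 ratio (the filter exists to prioritise high-affinity sites); the
number of assigned peaks is reported alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .iotables import DERecord, GeneModel, Peak

log = logging.getLogger(__name__)

__all__ = [
    "IntegrationConfig",
    "IntegratedGene",
    "OverlapResult",
    "assign_peaks_to_genes",
    "gene_binding_value",
    "de_significant",
    "combined_score",
    "integrate_and_rank",
    "overlap_counts",
]


@dataclass(frozen=True)
class IntegrationConfig:
    """Tunable parameters of the integration.

    Defaults are the published analysis settings: a 10 kb assignment
    window, binding cutoff 0.7 (log2 ratio), DE rule padj < 0.1 (or
    |shrunken log2FC| > 0.3 without replicates), and Combined Score
    weights 0.5 / 0.25 / 0.25.  ``flip_log2fc`` flips the sign of every
    fold change on input for callers whose tables are oriented
    control-vs-perturbed instead of perturbed-vs-control.
    """

    window_bp: int = 10_000
    binding_cutoff: float = 0.7
    de_padj_cutoff: float = 0.1
    no_replicate_mode: bool = False
    shrunken_lfc_cutoff: float = 0.3
    weights: tuple[float, float, float] = (0.5, 0.25, 0.25)
    direction: str = "both"
    neglog10_cap: float = 300.0
    flip_log2fc: bool = False

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be non-negative")
        if not 0.0 < self.de_padj_cutoff <= 1.0:
            raise ValueError("de_padj_cutoff must lie in (0, 1]")
        w = self.weights
        if len(w) != 3 or any(x < 0 for x in w):
            raise ValueError("weights must be three non-negative numbers")
        if not math.isclose(sum(w), 1.0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {sum(w)}")
        if self.direction not in {"up", "down", "both"}:
            raise ValueError(f"direction must be up/down/both, got {self.direction!r}")


@dataclass(frozen=True)
class IntegratedGene:
    """One ranked candidate target: binding and DE evidence plus the score."""

    gene_id: str
    binding_value: float
    n_peaks_assigned: int
    log2fc: float
    padj: float
    combined_score: float
    rank: int


def assign_peaks_to_genes(
    peaks: Iterable[Peak],
    genes: Iterable[GeneModel],
    window_bp: int = 10_000,
) -> dict[str, list[Peak]]:
    """Assign each peak to every gene it lies in or near.

    A peak is assigned to a gene iff the gap between the two intervals is
    at most ``window_bp`` (a gap of exactly ``window_bp`` counts: "within
    10 kb" is inclusive).  Peaks inside the gene body have gap 0.
    Assignment is strand-agnostic and a peak may hit several genes.
    Only genes with at least one assigned peak appear in the mapping.
    """
    genes = list(genes)
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - window_bp, g.end + window_bp, g.gene_id
        )
    assigned: dict[str, list[Peak]] = {}
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        # widen the query by 1 on each side so that *touching* the
        # window-extended gene interval (gap == window_bp exactly) counts
        for iv in tree.overlap(peak.start - 1, peak.end + 1):
            assigned.setdefault(iv.data, []).append(peak)
    for gene_id in assigned:
        assigned[gene_id].sort(key=lambda p: (p.chrom, p.start, p.end, p.peak_id))
    return assigned


def gene_binding_value(assigned_peaks: Sequence[Peak]) -> float | None:
    """Gene-level binding value: the maximum log2 ratio over assigned peaks
    (``None`` when no peak is assigned)."""
    if not assigned_peaks:
        return None
    return max(p.log2_ratio for p in assigned_peaks)


def de_significant(record: DERecord, config: IntegrationConfig) -> bool:
    """Is this gene differentially expressed under the configured rule?

    With replicates: padj present and strictly below the cutoff.  Without
    replicates: |shrunken log2FC| strictly above the cutoff.
    """
    if config.no_replicate_mode:
        return abs(record.log2fc) > config.shrunken_lfc_cutoff
    return record.padj is not None and record.padj < config.de_padj_cutoff


def combined_score(
    binding_value: float,
    log2fc: float,
    padj: float,
    config: IntegrationConfig | None = None,
) -> float:
    """Weighted Combined Score of binding and expression evidence.

    ``-log10(padj)`` is capped (default 300) so that floored zero
    p-values cannot dominate the ranking.
    """
    config = config or IntegrationConfig()
    if binding_value is None:
        raise ValueError("combined_score requires a binding value; filter first")
    if not padj > 0:
        raise ValueError("padj must be positive (zero p-values are floored on read)")
    w_b, w_f, w_p = config.weights
    neglog = min(-math.log10(padj), config.neglog10_cap)
    return w_b * binding_value + w_f * abs(log2fc) + w_p * neglog


def integrate_and_rank(
    de_table: Iterable[DERecord],
    peaks: Iterable[Peak],
    genes: Iterable[GeneModel],
    config: IntegrationConfig | None = None,
) -> list[IntegratedGene]:
    """Integrate binding and DE evidence and rank candidate direct targets.

    A gene is retained iff it (i) has at least one assigned peak,
    (ii) reaches the binding cutoff, (iii) is DE-significant, and
    (iv) matches the direction filter.  Output is sorted by score
    descending with the deterministic tie-break (binding desc, |log2FC|
    desc, gene_id asc) and ranked 1..N.
    """
    config = config or IntegrationConfig()
    genes = list(genes)
    gene_ids = {g.gene_id for g in genes}
    assigned = assign_peaks_to_genes(peaks, genes, config.window_bp)

    rows: list[tuple] = []
    n_unknown = n_missing_padj = 0
    for record in de_table:
        if record.gene_id not in gene_ids:
            n_unknown += 1
            continue
        lfc = -record.log2fc if config.flip_log2fc else record.log2fc
        gene_peaks = assigned.get(record.gene_id, [])
        binding = gene_binding_value(gene_peaks)
        if binding is None or binding < config.binding_cutoff:
            continue
        if not de_significant(record, config):
            continue
        if record.padj is None:
            n_missing_padj += 1  # cannot evaluate -log10(padj)
            continue
        if config.direction == "up" and not lfc > 0:
            continue
        if config.direction == "down" and not lfc < 0:
            continue
        score = combined_score(binding, lfc, record.padj, config)
        rows.append((score, binding, abs(lfc), record, len(gene_peaks), lfc))
    if n_unknown:
        log.warning("%d DE genes absent from the annotation were skipped", n_unknown)
    if n_missing_padj:
        log.warning("%d DE-significant genes lacked padj and were excluded", n_missing_padj)

    rows.sort(key=lambda r: (-r[0], -r[1], -r[2], r[3].gene_id))
    return [
        IntegratedGene(
            gene_id=rec.gene_id,
            binding_value=binding,
            n_peaks_assigned=n_peaks,
            log2fc=lfc,
            padj=rec.padj,
            combined_score=score,
            rank=rank,
        )
        for rank, (score, binding, _, rec, n_peaks, lfc) in enumerate(rows, start=1)
    ]


@dataclass
class OverlapResult:
    """Venn partition of published-target regulation across DE tables.

    ``qualifying`` maps table name -> genes (restricted to the query gene
    list) whose |fold change| reaches the cutoff; ``region_counts`` maps
    each non-empty subset of table names to the number of genes qualifying
    in exactly those tables; ``totals`` gives each table's qualifying count.
    """

    qualifying: dict[str, frozenset[str]]
    region_counts: dict[frozenset[str], int]
    totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.totals:
            self.totals = {name: len(s) for name, s in self.qualifying.items()}

    def count(self, *names: str) -> int:
        """Count of genes qualifying in exactly the named tables."""
        return self.region_counts.get(frozenset(names), 0)


def overlap_counts(
    de_tables: Mapping[str, Iterable[DERecord]],
    gene_list: Iterable[str],
    fold_cutoff: float = 2.0,
) -> OverlapResult:
    """Count, for a list of published target genes, how their regulation
    overlaps across several DE tables at a linear fold-change cutoff.

    A gene qualifies in a table iff |log2FC| >= log2(fold_cutoff)
    (direction-agnostic).  Requires at least two tables and a cutoff >= 1.
    """
    if len(de_tables) < 2:
        raise ValueError("overlap_counts needs at least 2 DE tables")
    if fold_cutoff < 1:
        raise ValueError("fold_cutoff must be >= 1 on the linear scale")
    gene_set = set(gene_list)
    log2_cut = math.log2(fold_cutoff)
    qualifying = {
        name: frozenset(
            r.gene_id
            for r in table
            if r.gene_id in gene_set and abs(r.log2fc) >= log2_cut
        )
        for name, table in de_tables.items()
    }
    names = list(qualifying)
    region_counts: dict[frozenset[str], int] = {}
    for mask in range(1, 2 ** len(names)):
        members = frozenset(n for i, n in enumerate(names) if mask >> i & 1)
        region = set.intersection(*(set(qualifying[n]) for n in members))
        for other in set(names) - members:
            region -= qualifying[other]
        region_counts[members] = len(region)
    return OverlapResult(qualifying, region_counts)
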