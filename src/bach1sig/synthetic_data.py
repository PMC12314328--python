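"""Seeded generators for synthetic study inputs.

Each generator emulates the statistical structure one stage of the
analysis assumes, with known ground truth, so every downstream stage can
be exercised and its recovery quantified without any sequencing data:

* :func:`simulate_annotation` — non-overlapping gene models on one
  chromosome.
* :func:`simulate_experiment` — a knockout-vs-wild-type design: planted
  true targets carry a high-ratio ChIP peak in or near the gene, strong
  up-regulation and a tiny adjusted p-value; null genes carry background
  peaks (ratios ~ Normal(0, sd), occasionally clearing the binding
  cutoff by chance) and null DE statistics with padj uniform on
  (0.1, 1] so the DE filter's boundary behaviour is unambiguous.
* :func:`simulate_compound_library` — DE profiles for a compound screen
  with planted "inhibitor" compounds that push the signature genes into
  the extreme top of the fold-change ranking.
* :func:`simulate_cell_panel` — a cell-line panel with a planted inverse
  linear relationship between regulator protein level and signature-gene
  expression, plus a shared factor giving positive gene-gene
  co-expression.
* :func:`simulate_promoter_sequences` — random-background DNA with the
  BACH-family consensus embedded at a known position per sequence.

All randomness flows through one :class:`numpy.random.Generator` seeded
from ``SimulationConfig.seed``; identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .iotables import (
    ConfigurationError,
    DERecord,
    ExpressionPanel,
    GeneModel,
    Peak,
)
from .motifscan import BACH_CONSENSUS
from .signature import CompoundProfile, DEFAULT_SIGNATURE, Signature

import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulatedExperiment",
    "simulate_annotation",
    "simulate_experiment",
    "simulate_compound_library",
    "simulate_cell_panel",
    "simulate_promoter_sequences",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generators.

    The defaults define the reference synthetic experiment used by the
    test-bench: 500 genes on a 20 Mb chromosome, 5 true targets with a
    planted binding ratio of 2.0 and log2FC of 3.0 (padj 1e-8), compound
    libraries of 50 profiles with 3 planted inhibitors, and 60-line
    panels with a planted regulator slope of -0.8 and noise SD 0.3.
    """

    seed: int = 0
    # annotation
    n_genes: int = 500
    chrom: str = "chr1"
    chrom_length_bp: int = 20_000_000
    gene_min_bp: int = 2_000
    gene_max_bp: int = 50_000
    # knockout experiment
    n_true_targets: int = 5
    true_binding_ratio: float = 2.0
    background_binding_ratio_sd: float = 0.3
    background_peak_fraction: float = 0.6
    true_log2fc: float = 3.0
    null_log2fc_sd: float = 0.5
    true_padj: float = 1e-8
    peak_width_bp: int = 200
    peak_tss_offset_bp: int = 5_000
    # compound library
    n_compounds: int = 50
    n_planted_inhibitors: int = 3
    compound_n_genes: int = 1_000
    # cell panel
    panel_n_lines: int = 60
    panel_slope: float = -0.8
    panel_noise_sd: float = 0.3
    panel_shared_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "chrom_length_bp",
            "n_true_targets",
            "n_compounds",
            "compound_n_genes",
            "panel_n_lines",
            "peak_width_bp",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in (
            "background_binding_ratio_sd",
            "null_log2fc_sd",
            "panel_noise_sd",
            "panel_shared_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_true_targets > self.n_genes:
            raise ConfigurationError("n_true_targets cannot exceed n_genes")
        if self.n_planted_inhibitors > self.n_compounds:
            raise ConfigurationError("n_planted_inhibitors cannot exceed n_compounds")
        if not 2 <= self.gene_min_bp <= self.gene_max_bp:
            raise ConfigurationError("need 2 <= gene_min_bp <= gene_max_bp")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class SimulatedExperiment:
    """One synthetic knockout-vs-wild-type experiment with ground truth."""

    genes: tuple[GeneModel, ...]
    peaks: tuple[Peak, ...]
    de_table: tuple[DERecord, ...]
    true_targets: frozenset[str]


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Place ``n_genes`` non-overlapping genes (lengths uniform in
    [gene_min_bp, gene_max_bp]) on one chromosome, separated by strictly
    positive gaps.  Raises :class:`ConfigurationError` if they cannot fit.
    """
    rng = config.rng() if rng is None else rng
    lengths = rng.integers(config.gene_min_bp, config.gene_max_bp + 1, config.n_genes)
    free = config.chrom_length_bp - int(lengths.sum())
    if free < config.n_genes + 1:
        raise ConfigurationError(
            f"{config.n_genes} genes totalling {int(lengths.sum())} bp cannot fit "
            f"with positive gaps in {config.chrom_length_bp} bp"
        )
    # distinct sorted offsets into the free space guarantee gaps >= 1 bp
    offsets = np.sort(rng.choice(free, size=config.n_genes, replace=False))
    starts = offsets + np.concatenate([[0], np.cumsum(lengths[:-1])])
    strands = rng.choice(["+", "-"], size=config.n_genes)
    return [
        GeneModel(
            gene_id=f"G{i + 1:04d}",
            chrom=config.chrom,
            start=int(starts[i]),
            end=int(starts[i] + lengths[i]),
            strand=str(strands[i]),
        )
        for i in range(config.n_genes)
    ]


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Simulate peaks, a DE table and truth labels for one experiment.

    True targets get one peak with log2 ratio >= ``true_binding_ratio``
    placed within ``peak_tss_offset_bp`` of the gene start (safely inside
    the default 10 kb assignment window), log2FC around
    ``true_log2fc`` (up in the knockout) and padj ``true_padj``.  If the
    planted effect size is zero the targets' padj is drawn from the null
    instead, so switching the effect off removes them from the DE filter.
    Null genes carry a background peak with probability
    ``background_peak_fraction`` and null DE statistics.
    """
    rng = config.rng()
    genes = simulate_annotation(config, rng)
    target_ids = frozenset(
        rng.choice([g.gene_id for g in genes], config.n_true_targets, replace=False)
    )

    effect_on = config.true_log2fc != 0
    peaks: list[Peak] = []
    de: list[DERecord] = []
    k = 0
    for gene in genes:
        is_target = gene.gene_id in target_ids
        if is_target or rng.random() < config.background_peak_fraction:
            if is_target:
                ratio = config.true_binding_ratio + abs(rng.normal(0.0, 0.15))
            else:
                ratio = rng.normal(0.0, config.background_binding_ratio_sd)
            offset = int(
                rng.integers(-config.peak_tss_offset_bp, config.peak_tss_offset_bp + 1)
            )
            start = max(0, gene.start + offset)
            k += 1
            peaks.append(
                Peak(f"pk{k:05d}", gene.chrom, start, start + config.peak_width_bp, ratio)
            )
        if is_target and effect_on:
            lfc = config.true_log2fc + rng.normal(0.0, 0.2)
            padj = config.true_padj
        else:
            lfc = rng.normal(0.0, config.null_log2fc_sd)
            padj = rng.uniform(0.1, 1.0)
        de.append(DERecord(gene.gene_id, float(lfc), float(padj)))
    return SimulatedExperiment(tuple(genes), tuple(peaks), tuple(de), target_ids)


def simulate_compound_library(
    config: SimulationConfig, signature: Signature = DEFAULT_SIGNATURE
) -> tuple[list[CompoundProfile], frozenset[str]]:
    """Simulate a compound screen: profiles over ``compound_n_genes`` genes
    (the signature genes plus fillers).

    Planted inhibitors place the signature genes far above the null
    fold-change distribution (log2FC ~ Uniform(4, 6) against a standard
    normal null) with padj < 1e-4; null compounds draw the signature
    genes from the same null as the fillers, i.e. uniform ranks.
    Returns the profiles and the set of planted compound ids.
    """
    rng = config.rng()
    n_fill = config.compound_n_genes - len(signature.genes)
    if n_fill < 0:
        raise ConfigurationError("compound_n_genes smaller than the signature")
    filler_ids = [f"CG{i + 1:05d}" for i in range(n_fill)]
    ids = [f"CPD{i + 1:03d}" for i in range(config.n_compounds)]
    planted = frozenset(rng.choice(ids, config.n_planted_inhibitors, replace=False))

    profiles: list[CompoundProfile] = []
    for cid in ids:
        lfc = rng.normal(0.0, 1.0, config.compound_n_genes)
        padj = rng.uniform(0.0, 1.0, config.compound_n_genes)
        records = []
        for i, gene in enumerate(list(signature.genes) + filler_ids):
            g_lfc, g_padj = float(lfc[i]), float(max(padj[i], 1e-12))
            if cid in planted and gene in signature.genes:
                g_lfc = float(rng.uniform(4.0, 6.0))
                g_padj = float(rng.uniform(1e-8, 1e-4))
            records.append(DERecord(gene, g_lfc, g_padj))
        profiles.append(CompoundProfile(cid, tuple(records)))
    return profiles, planted


def simulate_cell_panel(
    config: SimulationConfig,
    signature: Signature = DEFAULT_SIGNATURE,
    regulator: str = "BACH1",
) -> tuple[ExpressionPanel, dict]:
    """Simulate a cell-line panel with a planted inverse relationship.

    Regulator protein abundance is standard normal across lines; each
    signature gene's expression is ``baseline + panel_slope * regulator +
    shared + noise`` where the shared factor (SD ``panel_shared_sd``)
    induces positive gene-gene co-expression on top of the regulator
    effect.  Returns the panel and the truth (slope, noise SDs).
    """
    rng = config.rng()
    n = config.panel_n_lines
    reg = rng.normal(0.0, 1.0, n)
    shared = rng.normal(0.0, config.panel_shared_sd, n)
    expr = {}
    for i, gene in enumerate(signature.genes):
        baseline = 4.0 + i  # distinct log2(TPM+1) baselines per gene
        noise = rng.normal(0.0, config.panel_noise_sd, n)
        expr[gene] = baseline + config.panel_slope * reg + shared + noise
    lines = [f"LINE{i + 1:03d}" for i in range(n)]
    frame = pd.DataFrame(expr, index=pd.Index(lines, name="line_id"))
    protein = pd.Series(reg, index=frame.index, name=regulator)
    panel = ExpressionPanel(frame, protein, regulator)
    truth = {
        "slope": config.panel_slope,
        "noise_sd": config.panel_noise_sd,
        "shared_sd": config.panel_shared_sd,
    }
    return panel, truth


def simulate_promoter_sequences(
    config: SimulationConfig,
    n_sequences: int = 5,
    length: int = 300,
    motif: str = BACH_CONSENSUS,
) -> tuple[dict[str, str], dict[str, int]]:
    """Random uniform-background DNA with ``motif`` embedded once per
    sequence at a random position.  Returns the sequences and the planted
    0-based start positions."""
    rng = config.rng()
    if length < len(motif):
        raise ConfigurationError("sequence length shorter than the motif")
    seqs: dict[str, str] = {}
    positions: dict[str, int] = {}
    for i in range(n_sequences):
        bases = rng.choice(list("ACGT"), size=length)
        pos = int(rng.integers(0, length - len(motif) + 1))
        bases[pos : pos + len(motif)] = list(motif)
        name = f"region{i + 1}"
        seqs[name] = "".join(bases)
        positions[name] = pos
    return seqs, positions
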