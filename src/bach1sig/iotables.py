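"""Readers and writers for the external formats the pipeline touches.

Every genomic interval is normalised on read to a single internal
convention: 0-based, half-open ``[start, end)``.  BED files are native to
that convention; GTF gene rows (1-based, inclusive) are converted as they
are parsed.  Keeping one convention throughout means the ±10 kb
peak-to-gene window in :mod:`bach1sig.integrate` never has to reason about
off-by-one differences between input formats.

Supported formats
-----------------
* gene annotations: BED4+/BED6+ or minimal GTF (``gene`` rows only)
* ChIP peak tables: BED-like TSV with a per-peak log2 enrichment ratio
* differential-expression tables: DESeq2-style TSV (gene, log2FC, padj)
* JASPAR position frequency matrices (via :mod:`Bio.motifs`)
* FASTA (via :mod:`Bio.SeqIO`), alphabet restricted to ``ACGTN``
* cell-line expression panels: wide TSV, one row per line
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

log = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "Peak",
    "DERecord",
    "ExpressionPanel",
    "PositionFrequencyMatrix",
    "ParseError",
    "ValidationError",
    "ConfigurationError",
    "PADJ_FLOOR",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_peak_table",
    "write_peak_table",
    "read_de_table",
    "write_de_table",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_fasta",
    "write_fasta",
    "read_expression_panel",
    "write_expression_panel",
]

#: adjusted p-values of exactly zero are floored to this so that
#: -log10(padj) stays finite (the cap of 300 is applied at scoring time).
PADJ_FLOOR = 1e-300


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line/record."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (e.g. duplicate gene ids)."""


class ConfigurationError(ValueError):
    """The reader was configured inconsistently with the file's layout."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A named gene interval (0-based, half-open) on one chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A ChIP peak interval carrying a log2 enrichment ratio between conditions."""

    peak_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"peak {self.peak_id}: invalid interval [{self.start}, {self.end})"
            )
        if not math.isfinite(self.log2_ratio):
            raise ValidationError(f"peak {self.peak_id}: non-finite log2_ratio")


@dataclass(frozen=True)
class DERecord:
    """Per-gene differential-expression statistics.

    ``padj`` may be ``None`` (e.g. DESeq2 independent filtering); such
    records are excluded from significance calls and from the Combined
    Score downstream, since -log10(padj) cannot be evaluated.
    """

    gene_id: str
    log2fc: float
    padj: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("DE record with empty gene_id")
        if not math.isfinite(self.log2fc):
            raise ValidationError(f"{self.gene_id}: non-finite log2fc")
        if self.padj is not None and not (0.0 < self.padj <= 1.0):
            raise ValidationError(f"{self.gene_id}: padj {self.padj} outside (0, 1]")


@dataclass
class ExpressionPanel:
    """A cell-line panel: expression of named genes, optionally with the
    protein abundance of a named regulator per line.

    ``expression`` is lines x genes (log2[TPM+1] scale by convention);
    ``protein`` shares the line index.
    """

    expression: pd.DataFrame
    protein: pd.Series | None = None
    regulator: str | None = None

    def __post_init__(self) -> None:
        if self.expression.index.duplicated().any():
            raise ValidationError("expression panel has duplicated line ids")
        if not np.isfinite(self.expression.to_numpy(dtype=float)).all():
            raise ValidationError("expression panel contains non-finite values")
        if self.protein is not None and not self.protein.index.equals(
            self.expression.index
        ):
            raise ValidationError("protein series index does not match expression")

    @property
    def n_lines(self) -> int:
        return len(self.expression)


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Raw JASPAR-style motif counts: 4 x width, rows A, C, G, T."""

    name: str
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape[0] != 4 or counts.ndim != 2 or counts.shape[1] < 1:
            raise ValidationError(f"PFM {self.name}: counts must be 4 x width>=1")
        if (counts < 0).any():
            raise ValidationError(f"PFM {self.name}: negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

_GTF_GENE_ID = re.compile(r'gene_id[ =]+"?([^";]+)"?')


def read_gene_annotation(path: str | Path, format: str = "bed") -> list[GeneModel]:
    """Read a gene annotation from BED (>=4 columns) or minimal GTF.

    GTF coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.  Duplicate gene ids are rejected.
    """
    path = Path(path)
    if format not in {"bed", "gtf"}:
        raise ConfigurationError(f"unknown annotation format {format!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated toy files
                fields = line.split()
            try:
                if format == "bed":
                    if len(fields) < 4:
                        raise ParseError("expected >=4 BED columns")
                    chrom, start, end, gene_id = fields[:4]
                    strand = fields[5] if len(fields) >= 6 else "."
                    start_i, end_i = int(start), int(end)
                else:
                    if len(fields) < 9 or fields[2].lower() != "gene":
                        continue
                    chrom = fields[0]
                    start_i, end_i = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6] if fields[6] in {"+", "-"} else "."
                    m = _GTF_GENE_ID.search(fields[8])
                    if not m:
                        raise ParseError("gene row lacks a gene_id attribute")
                    gene_id = m.group(1)
                gene = GeneModel(gene_id, chrom, start_i, end_i, strand)
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path.name} line {lineno}: {exc}") from exc
            if gene.gene_id in seen:
                raise ValidationError(
                    f"{path.name} line {lineno}: duplicate gene_id {gene.gene_id!r}"
                )
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


def write_gene_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write genes as BED6 (score column fixed to 0)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------


def _looks_like_header(fields: Sequence[str]) -> bool:
    if len(fields) < 3:
        return False
    try:
        int(fields[1]), int(fields[2])
    except ValueError:
        return True
    return False


def read_peak_table(
    path: str | Path, ratio_column: str | int = "log2_ratio"
) -> list[Peak]:
    """Read a BED-like peak table carrying a per-peak log2 enrichment ratio.

    ``ratio_column`` names the ratio column when the file has a header, or
    is a 0-based column index for headerless files (default: column 4,
    the 5th field, when the default name is used on a headerless file).
    Rows whose ratio field is non-numeric (e.g. ``NA``) are dropped; the
    drop count is logged.  An empty file yields an empty list.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n")
        for ln in open(path)
        if ln.strip() and not ln.startswith(("#", "track", "browser"))
    ]
    if not lines:
        return []

    def _split(line: str) -> list[str]:
        fields = line.split("\t")
        return fields if len(fields) > 1 else line.split()

    first = _split(lines[0])
    header: list[str] | None = first if _looks_like_header(first) else None
    if header is not None:
        if isinstance(ratio_column, int):
            if not 0 <= ratio_column < len(header):
                raise ConfigurationError(f"ratio column index {ratio_column} out of range")
            ratio_idx = ratio_column
        elif ratio_column in header:
            ratio_idx = header.index(ratio_column)
        else:
            raise ConfigurationError(
                f"{path.name}: ratio column {ratio_column!r} not in header {header}"
            )
        body = lines[1:]
    else:
        ratio_idx = ratio_column if isinstance(ratio_column, int) else 4
        body = lines

    peaks: list[Peak] = []
    n_dropped = 0
    for lineno, line in enumerate(body, start=2 if header else 1):
        fields = _split(line)
        if ratio_idx >= len(fields):
            raise ConfigurationError(
                f"{path.name} line {lineno}: no ratio field at column {ratio_idx}"
            )
        try:
            ratio = float(fields[ratio_idx])
            if not math.isfinite(ratio):
                raise ValueError("non-finite")
        except ValueError:
            n_dropped += 1
            continue
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path.name} line {lineno}: {exc}") from exc
        peak_id = fields[3] if len(fields) > 3 and ratio_idx != 3 else f"peak{lineno}"
        try:
            peaks.append(Peak(peak_id, chrom, start, end, ratio))
        except ValidationError as exc:
            raise ParseError(f"{path.name} line {lineno}: {exc}") from exc
    if n_dropped:
        log.warning("%s: dropped %d rows with non-numeric ratio", path.name, n_dropped)
    return peaks


def write_peak_table(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tpeak_id\tlog2_ratio\n")
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.log2_ratio:g}\n")


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------

_GENE_ALIASES = ("gene_id", "gene", "symbol", "gene_name", "Gene")
_LFC_ALIASES = ("log2fc", "log2FoldChange", "lfc", "logFC")
_PADJ_ALIASES = ("padj", "adj_pvalue", "FDR", "qvalue", "adj.P.Val")


def _resolve(columns: Sequence[str], requested: str | None, aliases: Sequence[str], what: str) -> str:
    if requested is not None:
        if requested not in columns:
            raise ConfigurationError(f"{what} column {requested!r} not found in {list(columns)}")
        return requested
    for alias in aliases:
        if alias in columns:
            return alias
    raise ConfigurationError(f"no {what} column among {list(columns)} (tried {aliases})")


def read_de_table(
    path: str | Path,
    gene_column: str | None = None,
    lfc_column: str | None = None,
    padj_column: str | None = None,
) -> list[DERecord]:
    """Read a DESeq2-style differential-expression results table (TSV).

    Column names are resolved through common aliases unless given
    explicitly.  ``padj`` of exactly 0 is floored to :data:`PADJ_FLOOR`;
    missing padj (``NA``) is preserved as ``None``; rows with a missing
    log2 fold change are dropped (logged).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    gene_c = _resolve(df.columns, gene_column, _GENE_ALIASES, "gene_id")
    lfc_c = _resolve(df.columns, lfc_column, _LFC_ALIASES, "log2fc")
    padj_c = _resolve(df.columns, padj_column, _PADJ_ALIASES, "padj")
    records: list[DERecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        lfc = pd.to_numeric(getattr(row, lfc_c), errors="coerce")
        if pd.isna(lfc):
            n_dropped += 1
            continue
        padj_raw = pd.to_numeric(getattr(row, padj_c), errors="coerce")
        padj = None if pd.isna(padj_raw) else max(float(padj_raw), PADJ_FLOOR)
        records.append(DERecord(str(getattr(row, gene_c)), float(lfc), padj))
    if n_dropped:
        log.warning("%s: dropped %d rows with missing log2fc", path.name, n_dropped)
    return records


def write_de_table(records: Iterable[DERecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tpadj\n")
        for r in records:
            padj = "NA" if r.padj is None else repr(r.padj)
            fh.write(f"{r.gene_id}\t{r.log2fc!r}\t{padj}\n")


# ---------------------------------------------------------------------------
# JASPAR PFMs
# ---------------------------------------------------------------------------


def read_jaspar_pfm(path: str | Path) -> PositionFrequencyMatrix:
    """Read a JASPAR PFM (labelled ``jaspar`` or plain 4-row ``pfm`` layout).

    Row order is normalised to A, C, G, T.  Rows of unequal width raise
    :class:`ParseError`.  All-zero columns are accepted here; they are
    rejected (with zero pseudocount) when the log-odds matrix is built.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if not stripped:
        raise ParseError(f"{path.name}: empty PFM file")
    fmt = "jaspar" if stripped[0] in ">ACGT" and any(c.isalpha() for c in stripped.split("\n")[0]) else "pfm"
    try:
        with open(path) as fh:
            motif = bio_motifs.read(fh, fmt)
    except Exception as exc:  # biopython raises bare Exception on ragged rows
        raise ParseError(f"{path.name}: cannot parse as JASPAR PFM: {exc}") from exc
    widths = {len(motif.counts[b]) for b in "ACGT"}
    if len(widths) != 1:
        raise ParseError(f"{path.name}: PFM rows have unequal lengths {sorted(widths)}")
    counts = np.array([motif.counts[b] for b in "ACGT"], dtype=float)
    name = getattr(motif, "matrix_id", None) or motif.name or path.stem
    try:
        return PositionFrequencyMatrix(str(name), counts)
    except ValidationError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc


def write_jaspar_pfm(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pfm.name}\n")
        for base, row in zip("ACGT", pfm.counts):
            vals = " ".join(f"{v:g}" for v in row)
            fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_DNA_OK = set("ACGTN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {name: sequence} dict (upper-cased DNA).

    Characters outside ``ACGTN`` or an empty record body raise
    :class:`ParseError` naming the record.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path.name}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - _DNA_OK
        if bad:
            raise ParseError(
                f"{path.name}: record {rec.id!r} has non-IUPAC characters {sorted(bad)}"
            )
        out[rec.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# expression panels
# ---------------------------------------------------------------------------


def read_expression_panel(
    path: str | Path, regulator_column: str | None = None
) -> ExpressionPanel:
    """Read a wide TSV panel: first column line ids, remaining columns gene
    expression, optionally one column of regulator protein abundance."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    protein = None
    if regulator_column is not None:
        if regulator_column not in df.columns:
            raise ConfigurationError(
                f"regulator column {regulator_column!r} not in panel columns"
            )
        protein = df[regulator_column].astype(float)
        df = df.drop(columns=[regulator_column])
    return ExpressionPanel(df.astype(float), protein, regulator_column)


def write_expression_panel(panel: ExpressionPanel, path: str | Path) -> None:
    df = panel.expression.copy()
    if panel.protein is not None:
        df[panel.regulator or "protein"] = panel.protein
    df.to_csv(path, sep="\t", index_label="line_id")
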