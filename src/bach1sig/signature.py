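"""The BACH1 perturbation signature and its downstream applications.

The core signature is the coordinated induction of HMOX1, ZNF469 and
HTRA3 on depletion or inhibition of the repressor BACH1 (the extended
set adds NRCAM and FTH1).  This module applies a signature in four ways:

* :func:`perturbation_response` — did a perturbed-vs-control DE table
  induce the signature?  Genes absent from a table (a line may simply not
  express one signature gene) are reported as not-assayed rather than as
  failures.
* :func:`compound_concordance` — rank-based screening of compound DE
  profiles for candidate inhibitors: a candidate must place every
  signature gene found in the profile within the top ``top_fraction``
  of genes by log2 fold change *and* induce each of them past the fold /
  padj cutoffs.  This formalises "the signature genes are among the
  profile's most upregulated" as an auditable rule.
* :func:`basal_correlation` — test whether basal signature expression is
  inversely related to the regulator's protein level across a cell-line
  panel (Pearson r plus simple linear regression).
* :func:`ddct_fold_change` — comparative ddCt conversion of qPCR Ct
  values into fold changes for bench readout of the signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .iotables import DERecord, ExpressionPanel

__all__ = [
    "Signature",
    "CompoundProfile",
    "ConcordanceConfig",
    "ConcordanceResult",
    "GeneResponse",
    "PerturbationResponse",
    "BasalCorrelation",
    "UndefinedCorrelationError",
    "DEFAULT_SIGNATURE",
    "EXTENDED_SIGNATURE",
    "perturbation_response",
    "compound_concordance",
    "basal_correlation",
    "pairwise_signature_coexpression",
    "ddct_fold_change",
    "load_signature",
    "save_signature",
]


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (zero variance in one of the variables)."""


@dataclass(frozen=True)
class Signature:
    """An ordered set of gene symbols with the direction they move when the
    regulator is inhibited or depleted."""

    name: str
    genes: tuple[str, ...]
    direction_on_inhibition: str = "up"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        if self.direction_on_inhibition not in {"up", "down"}:
            raise ValueError("direction_on_inhibition must be 'up' or 'down'")
        object.__setattr__(self, "genes", tuple(self.genes))


#: the validated three-gene lung-cancer signature.
DEFAULT_SIGNATURE = Signature("bach1_core", ("HMOX1", "ZNF469", "HTRA3"))
#: the original top-five list before specificity pruning.
EXTENDED_SIGNATURE = Signature(
    "bach1_extended", ("HMOX1", "ZNF469", "HTRA3", "NRCAM", "FTH1")
)


@dataclass(frozen=True)
class CompoundProfile:
    """A treated-vs-vehicle DE profile for one compound."""

    compound_id: str
    records: tuple[DERecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.compound_id}: duplicated gene ids in profile")


def load_signature(path: str | Path) -> Signature:
    """Read a signature YAML: {name, genes: [...], direction_on_inhibition}.
    ``direction_on_knockout`` is accepted as a synonym (knockout and
    pharmacological inhibition move the signature the same way)."""
    data = yaml.safe_load(Path(path).read_text())
    direction = data.get(
        "direction_on_inhibition", data.get("direction_on_knockout", "up")
    )
    return Signature(data["name"], tuple(data["genes"]), direction)


def save_signature(signature: Signature, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "name": signature.name,
                "genes": list(signature.genes),
                "direction_on_inhibition": signature.direction_on_inhibition,
            },
            sort_keys=False,
        )
    )


# ---------------------------------------------------------------------------
# perturbation response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneResponse:
    gene: str
    assayed: bool
    induced: bool
    log2fc: float | None = None
    padj: float | None = None


@dataclass(frozen=True)
class PerturbationResponse:
    per_gene: tuple[GeneResponse, ...]
    n_assayed: int
    n_induced: int
    responds: bool


def _induced(record: DERecord, fold_cutoff: float, padj_cutoff: float | None) -> bool:
    if record.log2fc < math.log2(fold_cutoff):
        return False
    if padj_cutoff is None:
        return True
    return record.padj is not None and record.padj < padj_cutoff


def perturbation_response(
    de_table: Iterable[DERecord],
    signature: Signature = DEFAULT_SIGNATURE,
    fold_cutoff: float = 2.0,
    padj_cutoff: float | None = 0.05,
) -> PerturbationResponse:
    """Call whether a perturbed-vs-control DE table induces the signature.

    A gene is induced iff log2FC >= log2(fold_cutoff) and (if a padj
    cutoff is given) padj < padj_cutoff.  The overall call is true iff
    *all assayed* signature genes are induced; genes absent from the
    table are flagged not-assayed and do not count against the call.
    """
    by_gene = {r.gene_id: r for r in de_table}
    responses = []
    for gene in signature.genes:
        rec = by_gene.get(gene)
        if rec is None:
            responses.append(GeneResponse(gene, assayed=False, induced=False))
        else:
            responses.append(
                GeneResponse(
                    gene,
                    assayed=True,
                    induced=_induced(rec, fold_cutoff, padj_cutoff),
                    log2fc=rec.log2fc,
                    padj=rec.padj,
                )
            )
    assayed = [r for r in responses if r.assayed]
    n_induced = sum(r.induced for r in assayed)
    responds = bool(assayed) and n_induced == len(assayed)
    return PerturbationResponse(tuple(responses), len(assayed), n_induced, responds)


# ---------------------------------------------------------------------------
# compound screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceConfig:
    """Candidate rule for compound screening: signature genes must sit in
    the top ``top_fraction`` of the profile by log2FC and be induced past
    the fold / padj cutoffs."""

    fold_cutoff: float = 2.0
    padj_cutoff: float | None = 0.05
    top_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.fold_cutoff < 1:
            raise ValueError("fold_cutoff must be >= 1")


@dataclass(frozen=True)
class ConcordanceResult:
    compound_id: str
    n_signature_found: int
    n_induced: int
    mean_rank_percentile: float
    candidate: bool


def compound_concordance(
    profile: CompoundProfile,
    signature: Signature = DEFAULT_SIGNATURE,
    config: ConcordanceConfig | None = None,
) -> ConcordanceResult:
    """Score one compound profile for signature concordance.

    All genes are ranked by log2FC descending (average ranks on ties);
    ``mean_rank_percentile`` is the mean over found signature genes of
    1 - (rank - 1)/(N - 1), i.e. 1 when the signature occupies the very
    top of the profile.  ``candidate`` is true iff every found signature
    gene has rank <= top_fraction * N and is induced.  Invariant to any
    reordering of the input rows.
    """
    config = config or ConcordanceConfig()
    n = len(profile.records)
    if n < len(signature.genes):
        raise ValueError(
            f"{profile.compound_id}: profile has {n} genes, fewer than the "
            f"{len(signature.genes)}-gene signature"
        )
    lfc = np.array([r.log2fc for r in profile.records])
    ranks = stats.rankdata(-lfc, method="average")
    by_gene = {r.gene_id: (r, ranks[i]) for i, r in enumerate(profile.records)}

    found = [(g, *by_gene[g]) for g in signature.genes if g in by_gene]
    if not found:
        return ConcordanceResult(profile.compound_id, 0, 0, 0.0, False)
    sig_ranks = np.array([rank for _, _, rank in found])
    percentile = float(np.mean(1.0 - (sig_ranks - 1.0) / (n - 1.0))) if n > 1 else 1.0
    n_induced = sum(
        _induced(rec, config.fold_cutoff, config.padj_cutoff) for _, rec, _ in found
    )
    candidate = bool(
        (sig_ranks <= config.top_fraction * n).all() and n_induced == len(found)
    )
    return ConcordanceResult(
        profile.compound_id, len(found), n_induced, percentile, candidate
    )


# ---------------------------------------------------------------------------
# basal correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BasalCorrelation:
    pearson_r: float
    slope: float
    intercept: float
    p_value: float
    n: int


def _signature_scores(
    panel: ExpressionPanel, signature: Signature, method: str
) -> pd.Series:
    genes = [g for g in signature.genes if g in panel.expression.columns]
    if not genes:
        raise ValueError("no signature genes present in the panel")
    expr = panel.expression[genes]
    if method == "mean":
        return expr.mean(axis=1)
    if method == "zscore":
        sd = expr.std(axis=0, ddof=0)
        if (sd == 0).any():
            raise UndefinedCorrelationError(
                f"zero-variance signature gene(s): {list(sd.index[sd == 0])}"
            )
        return ((expr - expr.mean(axis=0)) / sd).mean(axis=1)
    raise ValueError(f"unknown score method {method!r}")


def basal_correlation(
    panel: ExpressionPanel,
    signature: Signature = DEFAULT_SIGNATURE,
    regulator_field: str | None = None,
    score_method: str = "zscore",
) -> BasalCorrelation:
    """Correlation between regulator protein level and basal signature score.

    The per-line signature score is the mean of per-gene z-scores across
    the panel (``score_method="mean"`` uses the plain mean of expression
    instead; use it when the slope must be interpretable on the raw
    expression scale).  Returns Pearson r, the least-squares slope and
    intercept of score on regulator, and the two-sided p-value for r.
    """
    if panel.protein is None:
        raise ValueError("panel carries no regulator protein abundance")
    if regulator_field is not None and panel.regulator not in (None, regulator_field):
        raise ValueError(
            f"panel regulator is {panel.regulator!r}, not {regulator_field!r}"
        )
    if panel.n_lines < 3:
        raise ValueError("need at least 3 lines for a correlation")
    score = _signature_scores(panel, signature, score_method)
    reg = panel.protein.astype(float)
    if np.std(reg) == 0 or np.std(score) == 0:
        raise UndefinedCorrelationError("zero variance in regulator or signature score")
    fit = stats.linregress(reg, score)
    return BasalCorrelation(
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n=panel.n_lines,
    )


def pairwise_signature_coexpression(
    panel: ExpressionPanel, signature: Signature = DEFAULT_SIGNATURE
) -> pd.DataFrame:
    """Pearson correlation matrix between signature genes across the panel
    (symmetric, unit diagonal; zero-variance genes yield NaN rows/columns)."""
    if panel.n_lines < 3:
        raise ValueError("need at least 3 lines for a correlation")
    genes = [g for g in signature.genes if g in panel.expression.columns]
    if len(genes) < 2:
        raise ValueError("need at least 2 signature genes present in the panel")
    return panel.expression[genes].corr(method="pearson")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def ddct_fold_change(
    ct_target_sample: float,
    ct_hk_sample: float,
    ct_target_ref: float,
    ct_hk_ref: float,
) -> float:
    """Comparative ddCt fold change: 2 ** -((Ct_t,s - Ct_hk,s) -
    (Ct_t,ref - Ct_hk,ref)), i.e. target expression normalised to a
    housekeeping gene (HPRT1 in the bench protocol) and to a reference
    sample.  ddCt = 0 gives 1.0; each unit drop in the sample's target Ct
    doubles the fold change."""
    for ct in (ct_target_sample, ct_hk_sample, ct_target_ref, ct_hk_ref):
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_hk_sample) - (ct_target_ref - ct_hk_ref)
    return 2.0 ** (-ddct)
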