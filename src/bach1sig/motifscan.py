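"""PWM scanning with exact p-values, in the style of FIMO.

A position frequency matrix (counts) is converted to a base-2 log-odds
position weight matrix against an i.i.d. background (uniform by default),
with a pseudocount distributed proportionally to the background.  Window
scores are sums of per-column log-odds.  The null distribution of the
window score under the background model is computed *exactly* by dynamic
programming over the columns on a discretised score lattice (default bin
width 1e-3 bits), and each window's p-value is the survival probability
P(S >= s) on that lattice.  Both strands can be scanned; reverse-strand
hits are reported in forward coordinates (1-based, inclusive).

Cells whose probability is zero (zero count with zero pseudocount) have
log-odds of -infinity; for the DP these are floored to a large negative
finite value (-100 bits) so the lattice stays finite.  The floor is far
below any attainable significant score and only matters for windows that
could never match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .iotables import PositionFrequencyMatrix

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "ScoreDistribution",
    "build_pwm",
    "exact_pvalue_table",
    "scan",
    "colocalize",
    "consensus_pfm",
    "reverse_complement",
    "BACH_CONSENSUS",
    "UNIFORM_BACKGROUND",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: BACH-family consensus ARE-like sequence (shared by BACH1 and BACH2).
BACH_CONSENSUS = "TGACTCAGC"

UNIFORM_BACKGROUND = np.full(4, 0.25)

#: finite stand-in for -infinity log-odds cells, in bits.
NEG_INF_FLOOR = -100.0

DEFAULT_GRANULARITY = 1e-3


class PWMBuildError(ValueError):
    """The counts cannot be turned into a valid probability matrix."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log-odds motif model (rows A, C, G, T; base-2) with its background."""

    name: str
    log_odds: np.ndarray = field(repr=False)
    background: np.ndarray = field(repr=False)
    pseudocount: float
    probabilities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        lo = np.asarray(self.log_odds, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        if lo.shape[0] != 4 or lo.ndim != 2 or lo.shape[1] < 1:
            raise PWMBuildError("log_odds must be 4 x width>=1")
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-12 or (bg <= 0).any():
            raise PWMBuildError("background must be 4 positive probabilities summing to 1")
        if np.abs(probs.sum(axis=0) - 1.0).max() > 1e-9:
            raise PWMBuildError("probability columns must sum to 1")
        object.__setattr__(self, "log_odds", lo)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "probabilities", probs)

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]

    def reverse_complement(self) -> "PositionWeightMatrix":
        """The same motif on the opposite strand (rows and columns reversed)."""
        return PositionWeightMatrix(
            name=self.name,
            log_odds=self.log_odds[::-1, ::-1].copy(),
            background=self.background,  # assumed strand-symmetric null
            pseudocount=self.pseudocount,
            probabilities=self.probabilities[::-1, ::-1].copy(),
        )


@dataclass(frozen=True)
class MotifHit:
    """A significant motif match, in forward 1-based inclusive coordinates.

    ``matched_text`` is the motif-strand sequence (reverse-complemented
    for minus-strand hits), as FIMO reports it.
    """

    sequence_name: str
    start: int
    stop: int
    strand: str
    score: float
    p_value: float
    matched_text: str


def build_pwm(
    pfm: PositionFrequencyMatrix | np.ndarray,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.1,
    name: str | None = None,
) -> PositionWeightMatrix:
    """Build a log-odds PWM from raw counts.

    Per column j: p(b, j) = (count(b, j) + pseudocount * background(b))
    / (colsum(j) + pseudocount); log-odds are log2(p / background).
    With ``pseudocount`` 0, zero-count cells get -infinity log-odds (the
    scanner floors them); an all-zero column with zero pseudocount is an
    error since its probabilities are undefined.
    """
    if isinstance(pfm, PositionFrequencyMatrix):
        counts = pfm.counts
        name = name or pfm.name
    else:
        counts = np.asarray(pfm, dtype=float)
        name = name or "pwm"
    if counts.shape[0] != 4 or counts.ndim != 2:
        raise PWMBuildError("counts must be a 4 x width matrix")
    if (counts < 0).any():
        raise PWMBuildError("counts must be non-negative")
    if pseudocount < 0:
        raise PWMBuildError("pseudocount must be >= 0")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-12 or (bg <= 0).any():
        raise PWMBuildError("background must be 4 positive probabilities summing to 1")
    colsums = counts.sum(axis=0)
    if pseudocount == 0 and (colsums == 0).any():
        raise PWMBuildError("all-zero column with zero pseudocount")
    probs = (counts + pseudocount * bg[:, None]) / (colsums + pseudocount)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probs / bg[:, None])
    return PositionWeightMatrix(name, log_odds, bg, pseudocount, probs)


@dataclass
class ScoreDistribution:
    """Exact null distribution of the window score on a discretised lattice.

    ``pmf[i]`` is the background probability of integer score
    ``min_int + i`` (in units of ``granularity`` bits); ``survival``
    is the corresponding P(S >= s).
    """

    granularity: float
    int_matrix: np.ndarray = field(repr=False)
    min_int: int
    pmf: np.ndarray = field(repr=False)
    survival: np.ndarray = field(repr=False)

    @property
    def max_int(self) -> int:
        return self.min_int + len(self.pmf) - 1

    def pvalue_int(self, int_score: int | np.ndarray) -> float | np.ndarray:
        """P(S >= int_score) under the background; 1 below the attainable
        minimum, 0 above the attainable maximum."""
        idx = np.clip(np.asarray(int_score) - self.min_int, 0, len(self.survival))
        padded = np.append(self.survival, 0.0)
        out = np.where(np.asarray(int_score) < self.min_int, 1.0, padded[idx])
        return float(out) if out.ndim == 0 else out

    def pvalue(self, score: float) -> float:
        """P(S >= score) for a score in bits (discretised like the windows)."""
        return float(self.pvalue_int(int(round(score / self.granularity))))

    def window_int_score(self, window_indices: Sequence[int]) -> int:
        return int(self.int_matrix[window_indices, range(len(window_indices))].sum())


def exact_pvalue_table(
    pwm: PositionWeightMatrix, granularity: float = DEFAULT_GRANULARITY
) -> ScoreDistribution:
    """Exact survival function of the per-window score under the background.

    Scores are discretised to integer multiples of ``granularity`` (bits,
    rounding to nearest); the DP convolves the four per-base score
    probabilities column by column, which is exact on the lattice.  The
    same discretised matrix scores the windows, so p-values are exact for
    the discretised scores (FIMO-like behaviour).
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    lo = np.where(np.isfinite(pwm.log_odds), pwm.log_odds, NEG_INF_FLOOR)
    int_matrix = np.rint(lo / granularity).astype(np.int64)
    bg = pwm.background

    col_mins = int_matrix.min(axis=0)
    pmf = np.ones(1)
    min_total = 0
    for j in range(pwm.width):
        col = int_matrix[:, j] - col_mins[j]
        width = int(col.max()) + 1
        new = np.zeros(len(pmf) + width - 1)
        for b in range(4):
            new[col[b] : col[b] + len(pmf)] += bg[b] * pmf
        pmf = new
        min_total += int(col_mins[j])
    survival = np.cumsum(pmf[::-1])[::-1]
    return ScoreDistribution(granularity, int_matrix, min_total, pmf, survival)


def _encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3 and anything else (N) to -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(len(seq), -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(encoded: np.ndarray, int_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores for every window, plus a validity mask (no N)."""
    w = int_matrix.shape[1]
    n_win = len(encoded) - w + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    scores = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    safe = np.clip(encoded, 0, 3)
    for j in range(w):
        col_bases = encoded[j : j + n_win]
        valid &= col_bases >= 0
        scores += int_matrix[safe[j : j + n_win], j]
    return scores, valid


def scan(
    sequences: Mapping[str, str],
    pwm: PositionWeightMatrix,
    p_threshold: float = 0.01,
    both_strands: bool = True,
    granularity: float = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """Scan sequences for significant motif matches.

    Every window of motif width on the requested strand(s) is scored;
    windows containing N are skipped; hits with exact p-value strictly
    below ``p_threshold`` are returned sorted by (sequence, start,
    strand).  Minus-strand windows are scored with the reverse-complement
    matrix against the forward sequence, which is equivalent to scanning
    the reverse strand, and use the same forward-model null (the
    background is strand-symmetric by assumption).
    """
    dist = exact_pvalue_table(pwm, granularity)
    matrices = {"+": dist.int_matrix}
    if both_strands:
        rc = pwm.reverse_complement()
        matrices["-"] = np.rint(
            np.where(np.isfinite(rc.log_odds), rc.log_odds, NEG_INF_FLOOR) / granularity
        ).astype(np.int64)

    hits: list[MotifHit] = []
    w = pwm.width
    for name in sequences:
        seq = sequences[name].upper()
        encoded = _encode(seq)
        for strand, matrix in matrices.items():
            scores, valid = _window_scores(encoded, matrix)
            if len(scores) == 0:
                continue
            pvals = dist.pvalue_int(scores)
            for i in np.nonzero(valid & (pvals < p_threshold))[0]:
                text = seq[i : i + w]
                hits.append(
                    MotifHit(
                        sequence_name=name,
                        start=int(i) + 1,
                        stop=int(i) + w,
                        strand=strand,
                        score=float(scores[i]) * granularity,
                        p_value=float(pvals[i]),
                        matched_text=text if strand == "+" else reverse_complement(text),
                    )
                )
    hits.sort(key=lambda h: (h.sequence_name, h.start, h.strand))
    return hits


def _hit_gap(a: MotifHit, b: MotifHit) -> int:
    """Bases strictly between two 1-based inclusive hit intervals (0 if they
    overlap or are adjacent)."""
    if b.start > a.stop:
        return b.start - a.stop - 1
    if a.start > b.stop:
        return a.start - b.stop - 1
    return 0


def colocalize(
    hits_a: Iterable[MotifHit],
    hits_b: Iterable[MotifHit],
    max_gap_bp: int = 0,
) -> list[tuple[MotifHit, MotifHit]]:
    """Pairs of hits (one from each list, same sequence) that overlap or lie
    within ``max_gap_bp`` of each other (a gap of exactly ``max_gap_bp``
    counts)."""
    by_seq: dict[str, list[MotifHit]] = {}
    for h in hits_b:
        by_seq.setdefault(h.sequence_name, []).append(h)
    pairs: list[tuple[MotifHit, MotifHit]] = []
    for a in hits_a:
        for b in by_seq.get(a.sequence_name, []):
            if _hit_gap(a, b) <= max_gap_bp:
                pairs.append((a, b))
    return pairs


def consensus_pfm(
    consensus: str, total: int = 100, dominant: int = 97, name: str | None = None
) -> PositionFrequencyMatrix:
    """A synthetic sharply-peaked PFM for a consensus sequence: the
    consensus base gets ``dominant`` counts per column, the other three
    bases share the remainder equally.  Useful for planted-motif tests and
    as a stand-in motif model when no curated matrix is at hand."""
    consensus = consensus.upper()
    if not consensus or set(consensus) - set(BASES):
        raise ValueError("consensus must be non-empty over ACGT")
    if not 0 < dominant <= total:
        raise ValueError("need 0 < dominant <= total")
    rest = (total - dominant) / 3.0
    counts = np.full((4, len(consensus)), rest)
    for j, base in enumerate(consensus):
        counts[_BASE_INDEX[base], j] = dominant
    return PositionFrequencyMatrix(name or f"synthetic_{consensus}", counts)
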