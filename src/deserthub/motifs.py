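"""Expression-filtered PWM scanning with exact p-values.

Position weight matrices of transcription factors expressed in the tissue
of interest (mean FPKM >= 2 across RNA-seq replicates) are scored against
both strands of a target sequence as log-odds in bits against a 0-order
GC-matched background.  P-values are exact: the null distribution of the
total log-odds score is computed by dynamic programming over scores
discretised at a fixed granularity (default 1e-3 bits), so a window's
p-value is the exact probability that a background-drawn word scores at
least as high.  Hits below the p-value cutoff (default 1e-4) are reported,
nested same-factor hits are pruned, and each hit is annotated with its
mean per-base conservation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomicInterval
from .io import BedGraph

__all__ = [
    "PWM",
    "MotifHit",
    "ScorePValueTable",
    "read_meme",
    "write_meme",
    "filter_expressed_tfs",
    "gc_matched_background",
    "score_pvalue_table",
    "scan_sequence",
    "prune_contained_motifs",
    "annotate_conservation",
    "hits_to_frame",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G


@dataclass(frozen=True)
class PWM:
    """A motif as a 4 x W column-stochastic probability matrix (ACGT rows)."""

    motif_id: str
    tf: str
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x W with W >= 1")
        if np.any(m < 0):
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def reverse_complement(self) -> "PWM":
        return replace(self, matrix=self.matrix[_COMP][:, ::-1])

    def consensus(self) -> str:
        return "".join("ACGT"[b] for b in np.argmax(self.matrix, axis=0))


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    motif_id: str
    tf: str
    score: float  # log-odds, bits
    pvalue: float
    conservation: float | None = None

    def __post_init__(self):
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"p-value outside (0, 1]: {self.pvalue}")


# ---------------------------------------------------------------------------
# MEME-like minimal text format
# ---------------------------------------------------------------------------


def read_meme(path) -> list[PWM]:
    """Parse letter-probability matrix blocks from a MEME-like file."""
    pwms = []
    motif_id = tf = None
    rows: list[list[float]] = []
    expect_rows = 0

    def _flush():
        nonlocal rows
        if motif_id is not None and rows:
            pwms.append(PWM(motif_id, tf or motif_id, np.array(rows).T))
        rows = []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                _flush()
                parts = line.split()
                motif_id = parts[1]
                tf = parts[2] if len(parts) > 2 else parts[1]
            elif line.startswith("letter-probability"):
                rows = []
            elif line and motif_id is not None:
                try:
                    vals = [float(x) for x in line.split()]
                except ValueError:
                    continue
                if len(vals) == 4:
                    rows.append(vals)
    _flush()
    return pwms


def write_meme(path, pwms: Iterable[PWM]) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id} {pwm.tf}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width}\n"
            )
            for col in pwm.matrix.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Expression filter and background
# ---------------------------------------------------------------------------


def filter_expressed_tfs(
    pwms: Sequence[PWM], expression: pd.DataFrame, min_fpkm: float = 2.0
) -> list[PWM]:
    """Keep PWMs whose TF has mean FPKM >= ``min_fpkm`` across replicates.

    The boundary is inclusive (mean exactly ``min_fpkm`` is kept); factors
    absent from the expression table are dropped.
    """
    if expression.empty:
        return []
    means = expression.mean(axis=1)
    return [
        pwm
        for pwm in pwms
        if pwm.tf in means.index and means[pwm.tf] >= min_fpkm
    ]


def gc_matched_background(sequence: str) -> np.ndarray:
    """0-order background with the scanned sequence's G+C fraction.

    Returns (pA, pC, pG, pT) with pG = pC = GC/2 and pA = pT = (1-GC)/2;
    the composition is strand-symmetric by construction.
    """
    counts = np.zeros(4)
    for base, idx in _BASE_INDEX.items():
        counts[idx] = sequence.count(base)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    gc = (counts[1] + counts[2]) / total
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


# ---------------------------------------------------------------------------
# Exact score -> p-value table
# ---------------------------------------------------------------------------


@dataclass
class ScorePValueTable:
    """Exact null distribution of a PWM's discretised log-odds score.

    ``survival[s - offset]`` is P(score_int >= s) under the background;
    integer scores are log-odds divided by ``granularity`` (bits), rounded
    to nearest.
    """

    granularity: float
    int_scores: np.ndarray  # 4 x W integer per-cell scores
    offset: int  # minimum achievable integer total score
    survival: np.ndarray

    @property
    def max_score(self) -> int:
        return self.offset + self.survival.size - 1

    def pvalue_of(self, int_score: int) -> float:
        if int_score <= self.offset:
            return 1.0
        if int_score > self.max_score:
            return 0.0
        return float(self.survival[int_score - self.offset])

    def threshold_for(self, p_cutoff: float) -> int:
        """Smallest integer score whose p-value is <= ``p_cutoff``."""
        idx = np.where(self.survival <= p_cutoff)[0]
        if idx.size == 0:
            return self.max_score + 1
        return self.offset + int(idx[0])


def log_odds_matrix(
    pwm: PWM, background: np.ndarray, pseudocount: float = 0.1
) -> np.ndarray:
    """Per-cell log2 odds with the pseudocount spread proportionally to
    the background: log2(((p + pc*bg) / (1 + pc)) / bg)."""
    bg = np.asarray(background, dtype=float)
    if not np.isclose(bg.sum(), 1.0, atol=1e-6):
        raise ValueError("background frequencies must sum to 1")
    zero_bg = bg == 0
    if np.any(zero_bg):
        if pseudocount == 0 and np.any(pwm.matrix[zero_bg] > 0):
            raise ValueError(
                "zero background frequency with non-zero motif probability "
                "and no pseudocount"
            )
        # a base the background never emits cannot contribute a hit
        bg = np.where(zero_bg, np.finfo(float).tiny, bg)
    num = (pwm.matrix + pseudocount * bg[:, None]) / (1.0 + pseudocount)
    return np.log2(num / bg[:, None])


def score_pvalue_table(
    pwm: PWM,
    background: np.ndarray,
    pseudocount: float = 0.1,
    granularity: float = 1e-3,
) -> ScorePValueTable:
    """Exact p-values by dynamic programming over discretised scores.

    Convolves the per-position score distributions under the background,
    then reverse-cumulates into a survival function.  ``p(s)`` is monotone
    non-increasing in s and ``p(min score) = 1``.
    """
    lo = log_odds_matrix(pwm, background, pseudocount)
    q = np.rint(lo / granularity).astype(np.int64)
    bg = np.asarray(background, dtype=float)
    offset = int(q.min(axis=0).sum())
    top = int(q.max(axis=0).sum())
    size = top - offset + 1
    pos_min = int(q[:, 0].min())
    dist = np.zeros(int(q[:, 0].max()) - pos_min + 1)
    for b in range(4):
        dist[q[b, 0] - pos_min] += bg[b]
    lo_cum = pos_min
    for k in range(1, pwm.width):
        kmin, kmax = int(q[:, k].min()), int(q[:, k].max())
        new = np.zeros(dist.size + (kmax - kmin))
        for b in range(4):
            shift = q[b, k] - kmin
            new[shift : shift + dist.size] += bg[b] * dist
        dist = new
        lo_cum += kmin
    # pad to the full theoretical range [offset, top]
    assert lo_cum == offset and dist.size == size
    survival = np.cumsum(dist[::-1])[::-1]
    survival = np.minimum(survival, 1.0)
    return ScorePValueTable(
        granularity=granularity, int_scores=q, offset=offset, survival=survival
    )


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def _encode(sequence: str) -> np.ndarray:
    codes = np.full(len(sequence), -1, dtype=np.int8)
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _window_scores(codes: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Integer score of every window; windows with non-ACGT bases get
    -inf (represented as the minimum int64)."""
    w = q.shape[1]
    if codes.size < w:
        return np.zeros(0, dtype=np.int64)
    wins = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (wins >= 0).all(axis=1)
    safe = np.where(wins >= 0, wins, 0)
    scores = np.take_along_axis(
        q.T[None, :, :], safe[:, :, None].astype(np.int64), axis=2
    )[:, :, 0].sum(axis=1)
    scores[~valid] = np.iinfo(np.int64).min
    return scores


def scan_sequence(
    sequence: str,
    pwms: Sequence[PWM],
    p_cutoff: float = 1e-4,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
    granularity: float = 1e-3,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Report every window on either strand with exact p-value <= cutoff.

    The background defaults to the GC-matched composition of the scanned
    sequence itself; because that background is strand-symmetric the same
    null distribution serves both strands, and hits on the '+' strand of a
    sequence equal the mirrored '-' hits on its reverse complement.
    """
    if background is None:
        background = gc_matched_background(sequence)
    codes = _encode(sequence)
    hits: list[MotifHit] = []
    for pwm in pwms:
        if pwm.width > len(sequence):
            continue
        table = score_pvalue_table(pwm, background, pseudocount, granularity)
        for strand, matrix_pwm in (("+", pwm), ("-", pwm.reverse_complement())):
            q = np.rint(
                log_odds_matrix(matrix_pwm, background, pseudocount)
                / granularity
            ).astype(np.int64)
            scores = _window_scores(codes, q)
            for pos in np.nonzero(scores > np.iinfo(np.int64).min)[0]:
                s = int(scores[pos])
                p = table.pvalue_of(s)
                if 0.0 < p <= p_cutoff:
                    hits.append(
                        MotifHit(
                            interval=GenomicInterval(
                                chrom,
                                offset + int(pos),
                                offset + int(pos) + pwm.width,
                            ),
                            strand=strand,
                            motif_id=pwm.motif_id,
                            tf=pwm.tf,
                            score=s * granularity,
                            pvalue=p,
                        )
                    )
    hits.sort(key=lambda h: (h.interval.start, h.interval.end, h.motif_id, h.strand))
    return hits


def prune_contained_motifs(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Drop hits nested inside a stronger, longer hit of the same factor.

    A hit is removed iff some hit of the same TF from a longer motif fully
    contains its interval and has a p-value at most as large.
    """
    kept = []
    for h in hits:
        redundant = any(
            other.tf == h.tf
            and other.interval.length() > h.interval.length()
            and other.interval.contains(h.interval)
            and other.pvalue <= h.pvalue
            for other in hits
        )
        if not redundant:
            kept.append(h)
    return kept


def annotate_conservation(
    hits: Sequence[MotifHit], conservation: BedGraph
) -> list[MotifHit]:
    """Mean per-base conservation over each hit (uncovered bases count 0)."""
    return [
        replace(h, conservation=conservation.mean_over(h.interval)) for h in hits
    ]


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": h.motif_id,
                "tf": h.tf,
                "chrom": h.interval.chrom,
                "start": h.interval.start,
                "end": h.interval.end,
                "strand": h.strand,
                "score_bits": h.score,
                "pvalue": h.pvalue,
                "mean_conservation": h.conservation,
            }
            for h in hits
        ]
    )
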