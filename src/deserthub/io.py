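"""Readers and writers for the plain-text formats the pipeline touches.

BED-family files are tab-delimited and 0-based half-open.  narrowPeak
columns 7-10 hold signalValue, -log10(p), -log10(q) and the summit offset;
q-values are converted to/from the linear scale of
:class:`~deserthub.core.ScoredInterval` at the file boundary.  BEDPE rows
carry the two mates in columns 1-6, name/score/strands in 7-10 and the two
mate MAPQs in extra columns 11-12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import FragmentMap, GenomicInterval, ScoredInterval

__all__ = [
    "FormatError",
    "ValidPair",
    "PairTable",
    "BedGraph",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bedgraph",
    "write_bedgraph",
    "read_bedpe",
    "write_bedpe",
    "read_fasta",
    "write_fasta",
    "read_expression_table",
    "write_expression_table",
    "read_fragment_bed",
    "write_fragment_bed",
]


class FormatError(ValueError):
    """A line-addressed file-format violation."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclass(frozen=True)
class ValidPair:
    """One uniquely mapped Hi-C di-tag (cis-only): two positions + MAPQs."""

    chrom: str
    pos1: int
    pos2: int
    mapq1: int = 60
    mapq2: int = 60


class PairTable:
    """Column-oriented container for valid read pairs on one chromosome.

    Iterating yields :class:`ValidPair` records; the numpy columns
    (``pos1``, ``pos2``, ``mapq1``, ``mapq2``) back all vectorised
    arithmetic downstream.
    """

    def __init__(self, chrom: str, pos1, pos2, mapq1=None, mapq2=None):
        self.chrom = chrom
        self.pos1 = np.asarray(pos1, dtype=np.int64)
        self.pos2 = np.asarray(pos2, dtype=np.int64)
        n = self.pos1.size
        if self.pos2.size != n:
            raise ValueError("pos1/pos2 length mismatch")
        self.mapq1 = (
            np.full(n, 60, dtype=np.int32)
            if mapq1 is None
            else np.asarray(mapq1, dtype=np.int32)
        )
        self.mapq2 = (
            np.full(n, 60, dtype=np.int32)
            if mapq2 is None
            else np.asarray(mapq2, dtype=np.int32)
        )
        if self.mapq1.size != n or self.mapq2.size != n:
            raise ValueError("mapq length mismatch")

    def __len__(self) -> int:
        return self.pos1.size

    def __iter__(self) -> Iterator[ValidPair]:
        for i in range(len(self)):
            yield ValidPair(
                self.chrom,
                int(self.pos1[i]),
                int(self.pos2[i]),
                int(self.mapq1[i]),
                int(self.mapq2[i]),
            )

    @classmethod
    def from_pairs(cls, chrom: str, pairs: Iterable[ValidPair]) -> "PairTable":
        rows = list(pairs)
        return cls(
            chrom,
            [p.pos1 for p in rows],
            [p.pos2 for p in rows],
            [p.mapq1 for p in rows],
            [p.mapq2 for p in rows],
        )


class BedGraph:
    """A sparse step track: sorted, non-overlapping scored intervals."""

    def __init__(self, chrom: str, starts, ends, values):
        self.chrom = chrom
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.values = np.asarray(values, dtype=float)
        if not (self.starts.size == self.ends.size == self.values.size):
            raise ValueError("column length mismatch")
        if np.any(self.ends <= self.starts):
            raise ValueError("empty or inverted bedGraph interval")
        order = np.argsort(self.starts, kind="stable")
        self.starts, self.ends, self.values = (
            self.starts[order],
            self.ends[order],
            self.values[order],
        )
        if self.starts.size > 1 and np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("overlapping bedGraph intervals")

    def __len__(self) -> int:
        return self.starts.size

    def mean_over(self, iv: GenomicInterval) -> float:
        """Arithmetic mean of the track over ``iv``; uncovered bases are 0."""
        if iv.chrom != self.chrom:
            return 0.0
        left = np.minimum(np.maximum(self.starts, iv.start), iv.end)
        right = np.minimum(np.maximum(self.ends, iv.start), iv.end)
        cov = np.maximum(right - left, 0)
        return float(np.dot(cov, self.values)) / iv.length()

    def sum_over(self, iv: GenomicInterval) -> float:
        return self.mean_over(iv) * iv.length()


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------


def _lines(path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_coords(path, lineno, fields) -> tuple[str, int, int]:
    if len(fields) < 3:
        raise FormatError(path, lineno, "fewer than 3 columns")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise FormatError(path, lineno, f"non-integer coordinates: {fields[1:3]}")
    if end <= start:
        raise FormatError(path, lineno, f"inverted/empty interval {start}-{end}")
    return fields[0], start, end


def read_bed(path) -> list[GenomicInterval]:
    out = []
    for lineno, f in _lines(path):
        chrom, start, end = _parse_coords(path, lineno, f)
        name = f[3] if len(f) > 3 and f[3] != "." else None
        strand = f[5] if len(f) > 5 and f[5] in "+-." else None
        out.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
    return out


def write_bed(path, intervals: Iterable[GenomicInterval], scores=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = iv.name or "."
            score = scores[i] if scores is not None else 0
            strand = iv.strand or "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n"
            )


def _q_to_neglog10(q: float | None) -> float:
    if q is None:
        return -1.0
    if q <= 0:
        return 999.0
    return -math.log10(q)


def read_narrowpeak(path) -> list[ScoredInterval]:
    out = []
    for lineno, f in _lines(path):
        chrom, start, end = _parse_coords(path, lineno, f)
        if len(f) < 10:
            raise FormatError(path, lineno, "narrowPeak needs 10 columns")
        try:
            signal = float(f[6])
            neglog_p = float(f[7])
            neglog_q = float(f[8])
        except ValueError:
            raise FormatError(path, lineno, f"non-numeric score fields: {f[6:9]}")
        q = None if neglog_q < 0 else 10.0 ** (-neglog_q)
        out.append(
            ScoredInterval(
                chrom,
                start,
                end,
                name=f[3] if f[3] != "." else None,
                strand=f[5] if f[5] in "+-." else None,
                score=neglog_p,
                qvalue=min(q, 1.0) if q is not None else None,
                signal=signal,
            )
        )
    return out


def write_narrowpeak(path, peaks: Iterable[ScoredInterval]) -> None:
    with open(path, "w") as fh:
        for pk in peaks:
            summit = pk.length() // 2
            fh.write(
                "\t".join(
                    [
                        pk.chrom,
                        str(pk.start),
                        str(pk.end),
                        pk.name or ".",
                        "0",
                        pk.strand or ".",
                        f"{pk.signal:.6g}",
                        f"{pk.score:.6g}",
                        f"{_q_to_neglog10(pk.qvalue):.6g}",
                        str(summit),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(path) -> BedGraph:
    chroms, starts, ends, values = [], [], [], []
    for lineno, f in _lines(path):
        chrom, start, end = _parse_coords(path, lineno, f)
        if len(f) < 4:
            raise FormatError(path, lineno, "bedGraph needs 4 columns")
        try:
            val = float(f[3])
        except ValueError:
            raise FormatError(path, lineno, f"non-numeric value: {f[3]!r}")
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
        values.append(val)
    if chroms and len(set(chroms)) > 1:
        raise FormatError(path, 0, "multi-chromosome bedGraph not supported")
    try:
        return BedGraph(chroms[0] if chroms else "", starts, ends, values)
    except ValueError as exc:
        raise FormatError(path, 0, str(exc))


def write_bedgraph(path, track: BedGraph) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(track.starts, track.ends, track.values):
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------


def read_bedpe(path) -> PairTable:
    chrom = None
    pos1, pos2, mq1, mq2 = [], [], [], []
    for lineno, f in _lines(path):
        if len(f) < 6:
            raise FormatError(path, lineno, "BEDPE needs at least 6 columns")
        c1, s1, e1 = _parse_coords(path, lineno, f[0:3])
        c2, s2, e2 = _parse_coords(path, lineno, f[3:6])
        if c1 != c2:
            raise FormatError(path, lineno, "trans pair in a cis-only pipeline")
        if chrom is None:
            chrom = c1
        elif chrom != c1:
            raise FormatError(path, lineno, "multi-chromosome BEDPE not supported")
        try:
            q1 = int(f[10]) if len(f) > 10 else 60
            q2 = int(f[11]) if len(f) > 11 else 60
        except ValueError:
            raise FormatError(path, lineno, f"non-integer MAPQ: {f[10:12]}")
        pos1.append(s1)
        pos2.append(s2)
        mq1.append(q1)
        mq2.append(q2)
    return PairTable(chrom or "", pos1, pos2, mq1, mq2)


def write_bedpe(path, pairs: PairTable, read_len: int = 50) -> None:
    with open(path, "w") as fh:
        for i in range(len(pairs)):
            p1, p2 = int(pairs.pos1[i]), int(pairs.pos2[i])
            fh.write(
                "\t".join(
                    [
                        pairs.chrom,
                        str(p1),
                        str(p1 + read_len),
                        pairs.chrom,
                        str(p2),
                        str(p2 + read_len),
                        f"pair_{i}",
                        "0",
                        "+",
                        "-",
                        str(int(pairs.mapq1[i])),
                        str(int(pairs.mapq2[i])),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA / expression tables / fragment maps
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_expression_table(path) -> pd.DataFrame:
    """TSV with a gene_id column followed by one FPKM column per replicate."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise FormatError(path, 1, "first column must be 'gene_id'")
    return df.set_index("gene_id")


def write_expression_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_fragment_bed(path) -> FragmentMap:
    ivs = read_bed(path)
    if not ivs:
        raise FormatError(path, 0, "empty fragment file")
    ivs.sort()
    boundaries = [ivs[0].start]
    for lineno, iv in enumerate(ivs, 1):
        if iv.start != boundaries[-1]:
            raise FormatError(path, lineno, "fragments do not tile the region")
        boundaries.append(iv.end)
    return FragmentMap(ivs[0].chrom, boundaries)


def write_fragment_bed(path, fragmap: FragmentMap) -> None:
    write_bed(path, iter(fragmap))
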