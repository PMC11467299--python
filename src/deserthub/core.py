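"""Genomic intervals, restriction-fragment maps and coordinate conventions.

Every coordinate inside the package is 0-based, half-open (BED convention).
Printed region strings of the form ``chr3:66337001-67337000`` are converted
at the parse/format boundary only; chromosome names are compared by exact
string equality (no ``chr`` stripping).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "ScoredInterval",
    "FragmentMap",
    "RegionParseError",
    "parse_ucsc_region",
    "format_ucsc_region",
    "merge_intervals",
]


class RegionParseError(ValueError):
    """Raised when a region string or interval does not parse/validate."""


_REGION_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``.

    Strand is carried for bookkeeping but ignored by all contact-map and
    peak arithmetic; only motif scanning consumes it.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def length_kb(self, ndigits: int = 0) -> float:
        """Length in kilobases, rounded to ``ndigits`` decimal places."""
        return round(self.length() / 1_000, ndigits)

    def length_mb(self, ndigits: int = 1) -> float:
        """Length in megabases, rounded to ``ndigits`` decimal places."""
        return round(self.length() / 1_000_000, ndigits)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def pad(self, left: int, right: int | None = None) -> "GenomicInterval":
        """Expand by ``left``/``right`` bp (clipped at zero)."""
        if right is None:
            right = left
        return replace(self, start=max(0, self.start - left), end=self.end + right)

    def __str__(self) -> str:
        return format_ucsc_region(self)


@dataclass(frozen=True, order=True)
class ScoredInterval(GenomicInterval):
    """An interval carrying peak-call attributes (score, q-value, signal)."""

    score: float = field(default=0.0, compare=False)
    qvalue: float | None = field(default=None, compare=False)
    signal: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.qvalue is not None and not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"q-value outside [0, 1]: {self.qvalue}")
        if self.signal < 0:
            raise ValueError(f"negative signal: {self.signal}")


def parse_ucsc_region(text: str) -> GenomicInterval:
    """Parse a printed ``chrom:start-end`` region string.

    The two printed integers are interpreted as a half-open span
    ``[start, end)``; the package applies one convention uniformly because
    printed sizes round identically at their stated precision either way.

    >>> parse_ucsc_region("chr3:66337001-67337000").length_mb()
    1.0
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise RegionParseError(f"malformed region string: {text!r}")
    start, end = int(m["start"]), int(m["end"])
    if start > end:
        raise RegionParseError(
            f"start exceeds end in {text!r}: {start} > {end}"
        )
    if start == end:
        raise RegionParseError(f"empty span in {text!r}: {start}-{end}")
    return GenomicInterval(m["chrom"], start, end)


def format_ucsc_region(iv: GenomicInterval) -> str:
    """Inverse of :func:`parse_ucsc_region` (half-open span printed as-is)."""
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is at most ``max_gap`` bp.

    Output is sorted and non-overlapping; the operation is idempotent and
    invariant to input order.  With ``max_gap=0`` this is classical interval
    union (book-ended intervals merge: the gap between ``[a,b)`` and
    ``[b,c)`` is zero).
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= max_gap
        ):
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


class FragmentMap:
    """Ordered restriction fragments tiling one chromosomal region.

    ``boundaries`` are the strictly increasing cut positions; fragment *i*
    spans ``[boundaries[i], boundaries[i+1])``, so the fragments tile the
    region with no gaps or overlaps and ``fragment_of`` is total on it.
    A position lying exactly on a cut site belongs to the fragment that
    starts there (half-open rule).
    """

    def __init__(self, chrom: str, boundaries: Sequence[int]):
        b = np.asarray(boundaries, dtype=np.int64)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need at least two boundaries (one fragment)")
        if not np.all(np.diff(b) > 0):
            raise ValueError("boundaries must be strictly increasing")
        self.chrom = chrom
        self.boundaries = b

    @property
    def n_fragments(self) -> int:
        return self.boundaries.size - 1

    @property
    def region(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, int(self.boundaries[0]), int(self.boundaries[-1])
        )

    def fragment_lengths(self) -> np.ndarray:
        return np.diff(self.boundaries)

    def fragment_of(self, pos: int | np.ndarray) -> np.ndarray:
        """Index of the fragment containing each position (vectorised)."""
        pos = np.asarray(pos, dtype=np.int64)
        if np.any(pos < self.boundaries[0]) or np.any(pos >= self.boundaries[-1]):
            raise ValueError("position outside the fragment map")
        return np.searchsorted(self.boundaries, pos, side="right") - 1

    def fragment(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            int(self.boundaries[i]),
            int(self.boundaries[i + 1]),
            name=f"frag_{i}",
        )

    def __len__(self) -> int:
        return self.n_fragments

    def __iter__(self):
        for i in range(self.n_fragments):
            yield self.fragment(i)
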