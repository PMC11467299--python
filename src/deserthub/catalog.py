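"""Multi-tissue putative-enhancer catalog construction.

Peak calls from many tissue-by-stage combinations are merged into one
master list, stitched when closer than 1 kb, annotated per combination
with the lowest overlapping peak q-value and with signal, filtered for
TSS proximity (+/- 2.5 kb window overlap), intersected with strong-
enhancer chromatin-state segments, and assigned to stringency tiers.
Missing q-values stay missing (NaN) so downstream heatmaps distinguish
"no peak" from "weak peak".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, ScoredInterval, merge_intervals
from .io import BedGraph

__all__ = [
    "CatalogRegion",
    "build_master_list",
    "annotate_min_q",
    "filter_tss_proximal",
    "intersect_strong_enhancers",
    "quantify_log2_rpkm",
    "tier_report",
    "build_catalog",
    "catalog_to_frame",
]


@dataclass
class CatalogRegion:
    """One stitched putative-enhancer region with per-combo annotation."""

    interval: GenomicInterval
    min_q: dict[str, float] = field(default_factory=dict)  # absent combo = no peak
    signal: dict[str, float] = field(default_factory=dict)  # log2 RPKM-like
    tss_distal: bool = True
    chromhmm_strong: bool = False
    tiers: set[str] = field(default_factory=set)


def _tree(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _overlapping(trees: Mapping[str, IntervalTree], iv: GenomicInterval):
    tree = trees.get(iv.chrom)
    if tree is None:
        return []
    return [hit.data for hit in tree.overlap(iv.start, iv.end)]


def build_master_list(
    peaks_by_combo: Mapping[str, Sequence[ScoredInterval]],
    stitch_gap: int = 1_000,
) -> list[GenomicInterval]:
    """Union of all combos' peaks, stitched when within ``stitch_gap`` bp.

    Deterministic and invariant to combo/peak input order; idempotent
    (rebuilding from the master list returns it unchanged).
    """
    all_peaks: list[GenomicInterval] = []
    for peaks in peaks_by_combo.values():
        all_peaks.extend(
            GenomicInterval(p.chrom, p.start, p.end) for p in peaks
        )
    return merge_intervals(all_peaks, max_gap=stitch_gap)


def annotate_min_q(
    regions: Sequence[GenomicInterval],
    peaks_by_combo: Mapping[str, Sequence[ScoredInterval]],
) -> list[CatalogRegion]:
    """Per region and combo, the lowest q-value among overlapping peaks.

    A combo with no overlapping peak is left absent (missing), never
    imputed to 1.
    """
    out = [CatalogRegion(interval=r) for r in regions]
    for combo, peaks in peaks_by_combo.items():
        trees = _tree(peaks)
        for reg in out:
            qs = [
                p.qvalue
                for p in _overlapping(trees, reg.interval)
                if p.qvalue is not None
            ]
            if qs:
                reg.min_q[combo] = min(qs)
    return out


def filter_tss_proximal(
    regions: Sequence[CatalogRegion],
    tss: Sequence[GenomicInterval],
    radius: int = 2_500,
) -> tuple[list[CatalogRegion], list[CatalogRegion]]:
    """Split regions into (distal, proximal) by TSS-window overlap.

    A region is proximal iff it overlaps any TSS +/- ``radius`` window;
    the flag is also recorded on each region.
    """
    windows = [t.pad(radius) for t in tss]
    trees = _tree(windows)
    distal, proximal = [], []
    for reg in regions:
        hit = bool(_overlapping(trees, reg.interval))
        reg.tss_distal = not hit
        (proximal if hit else distal).append(reg)
    return distal, proximal


def intersect_strong_enhancers(
    regions: Sequence[CatalogRegion],
    chromhmm_strong: Sequence[GenomicInterval],
) -> list[CatalogRegion]:
    """Flag regions overlapping (>= 1 bp) any strong-enhancer segment."""
    trees = _tree(chromhmm_strong)
    for reg in regions:
        reg.chromhmm_strong = bool(_overlapping(trees, reg.interval))
    return list(regions)


def quantify_log2_rpkm(
    read_count: float,
    region_length_bp: int,
    library_size: float,
    pseudocount: float = 1.0,
) -> float:
    """log2(RPKM + pseudocount) with RPKM = count / (kb * million reads)."""
    if region_length_bp <= 0 or library_size <= 0:
        raise ValueError("region length and library size must be positive")
    rpkm = read_count / ((region_length_bp / 1_000) * (library_size / 1_000_000))
    return math.log2(rpkm + pseudocount)


def annotate_signal(
    regions: Sequence[CatalogRegion],
    signal_by_combo: Mapping[str, BedGraph],
    log2: bool = True,
    pseudocount: float = 1.0,
) -> list[CatalogRegion]:
    """Mean track signal over each region per combo (optionally log2)."""
    for reg in regions:
        for combo, track in signal_by_combo.items():
            level = track.mean_over(reg.interval)
            reg.signal[combo] = (
                math.log2(level + pseudocount) if log2 else level
            )
    return list(regions)


def tier_report(
    regions: Sequence[CatalogRegion],
    tier_peaks: Mapping[str, Sequence[ScoredInterval]],
) -> dict[str, int]:
    """Per stringency tier, how many regions overlap >= 1 tier peak.

    Tier membership is recorded on each region; when tier peak sets are
    nested the counts are nested too.
    """
    counts = {}
    for tier, peaks in tier_peaks.items():
        trees = _tree(peaks)
        n = 0
        for reg in regions:
            if _overlapping(trees, reg.interval):
                reg.tiers.add(tier)
                n += 1
        counts[tier] = n
    return counts


def build_catalog(
    peaks_by_combo: Mapping[str, Sequence[ScoredInterval]],
    tss: Sequence[GenomicInterval],
    chromhmm_strong: Sequence[GenomicInterval] = (),
    signal_by_combo: Mapping[str, BedGraph] | None = None,
    stitch_gap: int = 1_000,
    tss_radius: int = 2_500,
) -> list[CatalogRegion]:
    """Master list -> min-q annotation -> TSS filter -> state intersection."""
    master = build_master_list(peaks_by_combo, stitch_gap)
    regions = annotate_min_q(master, peaks_by_combo)
    filter_tss_proximal(regions, tss, tss_radius)
    if chromhmm_strong:
        intersect_strong_enhancers(regions, chromhmm_strong)
    if signal_by_combo:
        annotate_signal(regions, signal_by_combo)
    return regions


def catalog_to_frame(
    regions: Sequence[CatalogRegion], combos: Sequence[str]
) -> pd.DataFrame:
    """Lossless region-by-combo table of q-values and signal."""
    rows = []
    for reg in regions:
        row: dict = {
            "chrom": reg.interval.chrom,
            "start": reg.interval.start,
            "end": reg.interval.end,
            "tss_distal": reg.tss_distal,
            "chromhmm_strong": reg.chromhmm_strong,
            "tiers": ",".join(sorted(reg.tiers)),
        }
        for combo in combos:
            row[f"q_{combo}"] = reg.min_q.get(combo, np.nan)
            row[f"signal_{combo}"] = reg.signal.get(combo, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
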