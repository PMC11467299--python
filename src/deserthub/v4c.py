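"""Virtual 4C: one-vs-all interaction profiles from Hi-C valid pairs.

A viewpoint-anchored profile is built in four stages: (1) keep pairs with
both MAPQs >= 30 and exactly one read inside the viewpoint; (2) count the
outside reads per restriction fragment; (3) distribute fragment counts into
fixed-width bins (default 3 kb) proportionally to the fragment/bin overlap;
(4) smooth by a centred moving average and scale to counts-per-million over
the region outside the viewpoint +/- an exclusion margin (default 5 kb).
Profiles from two conditions, scaled this way, subtract meaningfully.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import FragmentMap, GenomicInterval
from .io import BedGraph, PairTable

__all__ = [
    "V4CProfile",
    "select_informative_pairs",
    "count_per_fragment",
    "bin_fragment_counts",
    "smooth_profile",
    "scale_profile",
    "subtract_profiles",
    "viewpoint_profile",
    "profile_to_bedgraph",
]

SCALE_TARGET = 1_000_000.0  # counts-per-million over the non-excluded region


@dataclass(frozen=True)
class V4CProfile:
    """A binned viewpoint-interaction track.

    Bins of ``binsize`` bp are anchored at ``region.start``; the last bin
    may be truncated at ``region.end``.  ``excluded`` flags bins overlapping
    the viewpoint +/- the scaling-exclusion margin (set at the scaling
    stage; before that it flags viewpoint-overlapping bins only).
    ``stage`` is one of raw / smoothed / scaled / subtraction.
    """

    region: GenomicInterval
    viewpoint: GenomicInterval
    binsize: int
    values: np.ndarray
    excluded: np.ndarray
    stage: str = "raw"

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")
        if self.values.shape != self.excluded.shape:
            raise ValueError("values/excluded shape mismatch")

    @property
    def n_bins(self) -> int:
        return self.values.size

    def bin_edges(self) -> np.ndarray:
        edges = np.arange(self.region.start, self.region.end, self.binsize)
        return np.append(edges, self.region.end)

    def bin_interval(self, i: int) -> GenomicInterval:
        edges = self.bin_edges()
        return GenomicInterval(self.region.chrom, int(edges[i]), int(edges[i + 1]))

    def bin_of(self, pos: int) -> int:
        if not self.region.contains_pos(pos):
            raise ValueError(f"position {pos} outside region {self.region}")
        return (pos - self.region.start) // self.binsize


def _n_bins(region: GenomicInterval, binsize: int) -> int:
    return -(-region.length() // binsize)


def _viewpoint_bins(
    region: GenomicInterval, binsize: int, zone: GenomicInterval
) -> np.ndarray:
    """Boolean flag over bins overlapping ``zone``."""
    n = _n_bins(region, binsize)
    flags = np.zeros(n, dtype=bool)
    lo = max(0, (zone.start - region.start) // binsize)
    hi = min(n, -(-(zone.end - region.start) // binsize))
    flags[lo:hi] = True
    return flags


def select_informative_pairs(
    pairs: PairTable,
    viewpoint: GenomicInterval,
    region: GenomicInterval,
    min_mapq: int = 30,
) -> np.ndarray:
    """Positions of the outside mates of viewpoint-informative pairs.

    A pair is informative iff both MAPQs are at least ``min_mapq`` and
    exactly one of its two read positions lies inside the viewpoint
    interval (a pair with both reads inside is discarded).
    """
    if not region.contains(viewpoint):
        raise ValueError(f"viewpoint {viewpoint} outside region {region}")
    if pairs.chrom != viewpoint.chrom:
        raise ValueError("viewpoint chromosome does not match pairs")
    good_mapq = (pairs.mapq1 >= min_mapq) & (pairs.mapq2 >= min_mapq)
    in1 = (pairs.pos1 >= viewpoint.start) & (pairs.pos1 < viewpoint.end)
    in2 = (pairs.pos2 >= viewpoint.start) & (pairs.pos2 < viewpoint.end)
    keep = good_mapq & (in1 ^ in2)
    return np.where(in1[keep], pairs.pos2[keep], pairs.pos1[keep])


def count_per_fragment(positions: np.ndarray, fragmap: FragmentMap) -> np.ndarray:
    """Reads per restriction fragment; the total equals ``len(positions)``."""
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        return np.zeros(fragmap.n_fragments, dtype=np.int64)
    idx = fragmap.fragment_of(positions)
    return np.bincount(idx, minlength=fragmap.n_fragments).astype(np.int64)


def bin_fragment_counts(
    fragment_counts: np.ndarray,
    fragmap: FragmentMap,
    viewpoint: GenomicInterval,
    binsize: int = 3_000,
) -> V4CProfile:
    """Distribute fragment counts into fixed bins, proportionally on overlap.

    A fragment's count c is split as ``c * overlap_bp / fragment_len`` over
    every bin it overlaps, so the binned total equals the fragment total
    exactly (up to float round-off).
    """
    if binsize < 1:
        raise ValueError("binsize must be positive")
    region = fragmap.region
    n = _n_bins(region, binsize)
    values = np.zeros(n, dtype=float)
    counts = np.asarray(fragment_counts, dtype=float)
    if counts.size != fragmap.n_fragments:
        raise ValueError("fragment_counts length mismatch")
    starts = fragmap.boundaries[:-1]
    ends = fragmap.boundaries[1:]
    for k in np.nonzero(counts)[0]:
        fs, fe, c = int(starts[k]), int(ends[k]), counts[k]
        flen = fe - fs
        b0 = (fs - region.start) // binsize
        b1 = (fe - 1 - region.start) // binsize
        if b0 == b1:
            values[b0] += c
            continue
        for b in range(b0, b1 + 1):
            bin_start = region.start + b * binsize
            bin_end = min(bin_start + binsize, region.end)
            overlap = min(fe, bin_end) - max(fs, bin_start)
            values[b] += c * overlap / flen
    return V4CProfile(
        region=region,
        viewpoint=viewpoint,
        binsize=binsize,
        values=values,
        excluded=_viewpoint_bins(region, binsize, viewpoint),
        stage="raw",
    )


def smooth_profile(profile: V4CProfile, window_bins: int = 3) -> V4CProfile:
    """Centred moving average; the window shrinks symmetrically at edges."""
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window_bins == 1:
        return replace(profile, stage="smoothed")
    half = window_bins // 2
    v = profile.values
    n = v.size
    out = np.empty_like(v, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = (csum[i + k + 1] - csum[i - k]) / (2 * k + 1)
    return replace(profile, values=out, stage="smoothed")


def scale_profile(
    profile: V4CProfile, exclusion: int = 5_000, target: float = SCALE_TARGET
) -> V4CProfile:
    """Scale so the sum outside viewpoint +/- ``exclusion`` equals ``target``.

    Every bin (including the excluded zone) is multiplied by the same
    factor; bins overlapping the excluded zone are flagged in ``excluded``.
    """
    if exclusion < 0:
        raise ValueError("exclusion must be >= 0")
    zone = profile.viewpoint.pad(exclusion)
    excluded = _viewpoint_bins(profile.region, profile.binsize, zone)
    outside_sum = float(profile.values[~excluded].sum())
    if outside_sum <= 0:
        raise ValueError("profile is all zero outside the exclusion zone")
    factor = target / outside_sum
    return replace(
        profile, values=profile.values * factor, excluded=excluded, stage="scaled"
    )


def subtract_profiles(a: V4CProfile, b: V4CProfile) -> V4CProfile:
    """Signed difference a - b of two scaled profiles on the same grid."""
    if a.region != b.region or a.binsize != b.binsize or a.viewpoint != b.viewpoint:
        raise ValueError("profiles are not on the same grid/viewpoint")
    return replace(
        a,
        values=a.values - b.values,
        excluded=a.excluded | b.excluded,
        stage="subtraction",
    )


def viewpoint_profile(
    pairs: PairTable,
    fragmap: FragmentMap,
    viewpoint: GenomicInterval,
    binsize: int = 3_000,
    window_bins: int = 3,
    exclusion: int = 5_000,
    min_mapq: int = 30,
) -> V4CProfile:
    """Full pipeline: select, count, bin, smooth, scale."""
    outside = select_informative_pairs(pairs, viewpoint, fragmap.region, min_mapq)
    counts = count_per_fragment(outside, fragmap)
    raw = bin_fragment_counts(counts, fragmap, viewpoint, binsize)
    return scale_profile(smooth_profile(raw, window_bins), exclusion)


def profile_to_bedgraph(profile: V4CProfile) -> BedGraph:
    edges = profile.bin_edges()
    return BedGraph(profile.region.chrom, edges[:-1], edges[1:], profile.values)
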