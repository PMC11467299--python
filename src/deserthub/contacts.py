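"""Binned contact matrices: filtering, balancing, subtraction, insulation.

Raw symmetric count matrices are built from valid pairs at a fixed bin size
(default 5 kb).  Low-coverage bins are masked (never silently zeroed) by a
non-zero-count floor and a MAD-based outlier rule on the log marginal, then
the retained submatrix is balanced by iterative correction so every
retained marginal is equal, yielding per-bin bias factors with
``balanced_ij = bias_i * raw_ij * bias_j``.  Insulation is the mean
balanced contact in a diamond window sliding along the diagonal; TAD
boundaries are local minima of the z-scored multi-window insulation
profile, classified strong/weak by a one-sided Wilcoxon rank-sum test of
boundary-diamond against flank-diamond contact values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval
from .io import PairTable

__all__ = [
    "ContactMatrix",
    "Boundary",
    "InsulationResult",
    "bin_pairs",
    "filter_bins",
    "balance_matrix",
    "subtract_matrices",
    "insulation_and_boundaries",
    "interdomain_insulation_matrix",
    "write_matrix",
    "read_matrix",
]


@dataclass
class ContactMatrix:
    """A symmetric binned contact map with a per-bin retention mask."""

    region: GenomicInterval
    binsize: int
    matrix: np.ndarray
    mask: np.ndarray  # True = retained
    stage: str = "raw"
    bias: np.ndarray | None = None
    ignore_diags: int = 0

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        finite = np.isfinite(m)
        sym_ok = np.allclose(
            np.where(finite, m, 0.0), np.where(finite.T, m.T, 0.0), atol=1e-9
        ) and np.array_equal(finite, finite.T)
        if not sym_ok:
            raise ValueError("matrix must be symmetric")
        if self.mask.shape != (m.shape[0],):
            raise ValueError("mask length mismatch")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_edges(self) -> np.ndarray:
        edges = np.arange(self.region.start, self.region.end, self.binsize)
        return np.append(edges, self.region.end)

    def bin_of(self, pos: int) -> int:
        if not self.region.contains_pos(pos):
            raise ValueError(f"position {pos} outside region {self.region}")
        return (pos - self.region.start) // self.binsize

    def bin_range(self, iv: GenomicInterval) -> tuple[int, int]:
        """Half-open bin-index range of bins overlapping ``iv``."""
        lo = max(0, (iv.start - self.region.start) // self.binsize)
        hi = min(self.n_bins, -(-(iv.end - self.region.start) // self.binsize))
        return int(lo), int(hi)

    def values_with_mask(self) -> np.ndarray:
        """Matrix with masked rows/columns (and ignored diagonals) as NaN."""
        out = self.matrix.astype(float).copy()
        out[~self.mask, :] = np.nan
        out[:, ~self.mask] = np.nan
        n = self.n_bins
        for k in range(self.ignore_diags):
            idx = np.arange(n - k)
            out[idx, idx + k] = np.nan
            out[idx + k, idx] = np.nan
        return out


def bin_pairs(
    pairs: PairTable, region: GenomicInterval, binsize: int = 5_000
) -> ContactMatrix:
    """Accumulate pairs into a symmetric raw count matrix.

    Each pair increments one unordered cell (mirrored off-diagonal); the
    sum over the upper triangle including the diagonal equals the number
    of pairs inside the region.
    """
    n = -(-region.length() // binsize)
    m = np.zeros((n, n), dtype=np.int64)
    if len(pairs):
        inside = (
            (pairs.pos1 >= region.start)
            & (pairs.pos1 < region.end)
            & (pairs.pos2 >= region.start)
            & (pairs.pos2 < region.end)
        )
        bi = (pairs.pos1[inside] - region.start) // binsize
        bj = (pairs.pos2[inside] - region.start) // binsize
        lo = np.minimum(bi, bj)
        hi = np.maximum(bi, bj)
        np.add.at(m, (lo, hi), 1)
        upper = np.triu(m, 1)
        m = m + upper.T
    return ContactMatrix(
        region=region,
        binsize=binsize,
        matrix=m,
        mask=np.ones(n, dtype=bool),
        stage="raw",
    )


def filter_bins(
    cm: ContactMatrix,
    min_nnz: int = 10,
    mad_max: float = 5.0,
    min_count: float = 0.0,
) -> ContactMatrix:
    """Mask under-covered bins before balancing.

    A bin is masked if it has fewer than ``min_nnz`` non-zero cells, a
    marginal below ``min_count``, or a log10 marginal more than ``mad_max``
    median-absolute-deviations below the median log10 marginal of
    non-empty bins.
    """
    m = cm.matrix
    nnz = (m > 0).sum(axis=1)
    marginal = m.sum(axis=1).astype(float)
    keep = (nnz >= min_nnz) & (marginal >= min_count) & (marginal > 0)
    pos = marginal > 0
    if pos.any():
        logm = np.log10(marginal[pos])
        med = np.median(logm)
        mad = np.median(np.abs(logm - med))
        cutoff = med - mad_max * mad
        low = np.zeros(cm.n_bins, dtype=bool)
        low[pos] = np.log10(marginal[pos]) < cutoff
        keep &= ~low
    return replace(cm, mask=cm.mask & keep)


def balance_matrix(
    cm: ContactMatrix,
    tol: float = 1e-5,
    max_iters: int = 200,
    ignore_diags: int = 2,
) -> ContactMatrix:
    """Iterative correction of a masked raw matrix.

    Alternately rescales by the current marginals (computed over retained
    bins, excluding the first ``ignore_diags`` diagonals) until their
    variance across retained bins drops below ``tol``.  The returned
    matrix satisfies ``balanced_ij = bias_i * raw_ij * bias_j`` on all
    cells; retained marginals (ignored diagonals excluded) equal 1.
    """
    if not cm.mask.any():
        raise ValueError("no retained bins to balance")
    n = cm.n_bins
    raw = cm.matrix.astype(float)
    work = raw.copy()
    work[~cm.mask, :] = 0.0
    work[:, ~cm.mask] = 0.0
    for k in range(ignore_diags):
        idx = np.arange(n - k)
        work[idx, idx + k] = 0.0
        work[idx + k, idx] = 0.0
    bias = np.ones(n, dtype=float)
    retained = cm.mask.copy()
    # bins with an empty working marginal cannot be balanced: mask them
    retained &= work.sum(axis=1) > 0
    if not retained.any():
        raise ValueError("no balanceable bins (all marginals empty)")
    for _ in range(max_iters):
        marg = bias * (work @ bias)
        mean = marg[retained].mean()
        s = np.where(retained, marg / mean, 1.0)
        if float(np.var(s[retained])) < tol:
            break
        bias = np.where(retained, bias / np.sqrt(np.where(s > 0, s, 1.0)), bias)
    # normalise so retained marginals equal one
    marg = bias * (work @ bias)
    mean = marg[retained].mean()
    if mean > 0:
        bias /= np.sqrt(mean)
    bias = np.where(retained, bias, np.nan)
    balanced = np.outer(np.nan_to_num(bias), np.nan_to_num(bias)) * raw
    return ContactMatrix(
        region=cm.region,
        binsize=cm.binsize,
        matrix=balanced,
        mask=retained,
        stage="balanced",
        bias=bias,
        ignore_diags=ignore_diags,
    )


def subtract_matrices(a: ContactMatrix, b: ContactMatrix) -> ContactMatrix:
    """Elementwise difference a - b of balanced maps on the same grid.

    Bins masked in either input are masked in the output; masked cells
    propagate as missing, never as zero.
    """
    if a.stage != "balanced" or b.stage != "balanced":
        raise ValueError("subtraction requires balanced matrices")
    if a.region != b.region or a.binsize != b.binsize:
        raise ValueError("matrices are not on the same grid")
    mask = a.mask & b.mask
    diff = a.matrix - b.matrix
    return ContactMatrix(
        region=a.region,
        binsize=a.binsize,
        matrix=diff,
        mask=mask,
        stage="subtraction",
        ignore_diags=max(a.ignore_diags, b.ignore_diags),
    )


@dataclass(frozen=True)
class Boundary:
    bin: int
    interval: GenomicInterval
    score: float  # TAD-separation score at the minimum
    pvalue: float
    qvalue: float
    cls: str  # strong / weak / ns


@dataclass
class InsulationResult:
    windows: list[int]  # window sizes, bp
    insulation: np.ndarray  # z-scored, one row per window (NaN at edges)
    tad_separation: np.ndarray
    boundaries: list[Boundary] = field(default_factory=list)

    def called(self, classes=("strong", "weak")) -> list[Boundary]:
        return [b for b in self.boundaries if b.cls in classes]


def _diamond(values: np.ndarray, i: int, w: int) -> np.ndarray:
    """Cells of the w x w diamond spanning bins (i-w..i) x (i..i+w)."""
    return values[i - w : i, i : i + w].ravel()


def insulation_and_boundaries(
    cm: ContactMatrix,
    min_window: int = 50_000,
    threshold: float = 0.05,
    delta: float = 0.01,
) -> InsulationResult:
    """Multi-window diamond insulation, TAD-separation score, boundaries.

    Windows are {1x, 2x, 3x} ``min_window``.  Per window the mean balanced
    contact in the diamond upstream-x-downstream of each bin is z-scored;
    the TAD-separation score averages the z-scores across windows.  A
    candidate boundary is a local minimum at least ``delta`` below both
    flanking maxima; its p-value is a one-sided rank-sum test of the
    pooled boundary-diamond cells against the pooled diamond cells at the
    two flanking maxima, BH-corrected across candidates.
    """
    if cm.stage != "balanced":
        raise ValueError("insulation requires a balanced matrix")
    if cm.region.length() < 2 * min_window:
        raise ValueError("matrix narrower than twice the minimal window")
    values = cm.values_with_mask()
    n = cm.n_bins
    w0 = max(1, min_window // cm.binsize)
    window_bins = [w0, 2 * w0, 3 * w0]
    ins = np.full((3, n), np.nan)
    for r, w in enumerate(window_bins):
        for i in range(w, n - w):
            cells = _diamond(values, i, w)
            if np.isfinite(cells).any():
                ins[r, i] = np.nanmean(cells)
        row = ins[r]
        finite = np.isfinite(row)
        if finite.sum() > 1:
            mu, sd = row[finite].mean(), row[finite].std()
            if sd > 0:
                ins[r] = (row - mu) / sd
            else:
                ins[r] = row - mu
    finite_rows = np.isfinite(ins)
    counts = finite_rows.sum(axis=0)
    tad_sep = np.full(n, np.nan)
    any_row = counts > 0
    tad_sep[any_row] = (
        np.where(finite_rows, ins, 0.0).sum(axis=0)[any_row] / counts[any_row]
    )

    # candidate local minima with prominence >= delta on each side
    candidates = []
    finite_idx = np.where(np.isfinite(tad_sep))[0]
    for i in finite_idx:
        left = tad_sep[max(0, i - 1)] if i > 0 else np.nan
        right = tad_sep[i + 1] if i + 1 < n else np.nan
        if not (np.isfinite(left) and np.isfinite(right)):
            continue
        if not (tad_sep[i] <= left and tad_sep[i] <= right):
            continue
        if tad_sep[i] == left and i > 0:  # plateau: keep leftmost bin only
            continue
        lmax = _flank_max(tad_sep, i, -1)
        rmax = _flank_max(tad_sep, i, +1)
        if lmax is None or rmax is None:
            continue
        li, lv = lmax
        ri, rv = rmax
        if min(lv, rv) - tad_sep[i] < delta:
            continue
        candidates.append((i, li, ri))

    boundaries: list[Boundary] = []
    if candidates:
        pvals = []
        for i, li, ri in candidates:
            at_min, at_flank = [], []
            for w in window_bins:
                if not (w <= i < n - w):
                    continue  # diamond would truncate at the matrix edge
                at_min.append(_diamond(values, i, w))
                for f in (li, ri):
                    if w <= f < n - w:
                        at_flank.append(_diamond(values, f, w))
            at_min = (
                np.concatenate(at_min) if at_min else np.array([], dtype=float)
            )
            at_min = at_min[np.isfinite(at_min)]
            at_flank = (
                np.concatenate(at_flank) if at_flank else np.array([], dtype=float)
            )
            at_flank = at_flank[np.isfinite(at_flank)]
            if at_min.size == 0 or at_flank.size == 0:
                pvals.append(1.0)
                continue
            res = stats.mannwhitneyu(at_min, at_flank, alternative="less")
            pvals.append(float(res.pvalue))
        _, qvals, _, _ = multipletests(pvals, alpha=threshold, method="fdr_bh")
        edges = cm.bin_edges()
        for (i, _, _), p, q in zip(candidates, pvals, qvals):
            cls = "strong" if p < 0.01 else ("weak" if p < 0.05 else "ns")
            boundaries.append(
                Boundary(
                    bin=i,
                    interval=GenomicInterval(
                        cm.region.chrom, int(edges[i]), int(edges[i + 1])
                    ),
                    score=float(tad_sep[i]),
                    pvalue=p,
                    qvalue=float(q),
                    cls=cls,
                )
            )
    return InsulationResult(
        windows=[w * cm.binsize for w in window_bins],
        insulation=ins,
        tad_separation=tad_sep,
        boundaries=boundaries,
    )


def _flank_max(score: np.ndarray, i: int, step: int):
    """Nearest local maximum of a profile walking from i in ``step``."""
    n = score.size
    j = i + step
    best = None
    while 0 <= j < n and np.isfinite(score[j]):
        if best is None or score[j] >= best[1]:
            best = (j, score[j])
        else:
            break  # started descending: previous point was the local max
        j += step
    return best


def interdomain_insulation_matrix(
    cm: ContactMatrix, domains: list[GenomicInterval]
) -> np.ndarray:
    """Distance-normalised, z-scored mean contact between domain blocks.

    Entry (p, q) is the mean contact over the p x q block divided by the
    distance-expected mean (the average value at the same bin separations
    over the whole matrix), then z-normalised across the unique entries.
    Symmetric by construction.

    Works on any stage, but a raw (mask-filtered) matrix is the intended
    input for detecting condition-specific dense blocks: iterative
    correction equalises bin marginals and in doing so largely cancels the
    very density contrast this matrix is meant to display, whereas the
    per-diagonal expectation already removes the distance effect that
    balancing would otherwise be needed for.
    """
    values = cm.values_with_mask()
    n = cm.n_bins
    # distance-expected mean per diagonal offset
    exp = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(values, offset=d)
        if np.isfinite(diag).any():
            exp[d] = np.nanmean(diag)
    k = len(domains)
    oe = np.full((k, k), np.nan)
    ranges = [cm.bin_range(dom) for dom in domains]
    for p in range(k):
        for q in range(p, k):
            (a0, a1), (b0, b1) = ranges[p], ranges[q]
            block = values[a0:a1, b0:b1]
            if block.size == 0 or not np.isfinite(block).any():
                continue
            ii, jj = np.meshgrid(
                np.arange(a0, a1), np.arange(b0, b1), indexing="ij"
            )
            eblock = exp[np.abs(ii - jj)]
            good = np.isfinite(block) & np.isfinite(eblock) & (eblock > 0)
            if not good.any():
                continue
            oe[p, q] = oe[q, p] = float(
                np.nanmean(block[good]) / np.nanmean(eblock[good])
            )
    iu = np.triu_indices(k)
    vals = oe[iu]
    finite = np.isfinite(vals)
    if finite.sum() > 1 and np.nanstd(vals[finite]) > 0:
        z = (oe - np.nanmean(vals[finite])) / np.nanstd(vals[finite])
    else:
        z = oe - (np.nanmean(vals[finite]) if finite.any() else 0.0)
    return z


# ---------------------------------------------------------------------------
# Two-file text I/O: bin table (BED3 + bin_id + mask) and triplets
# ---------------------------------------------------------------------------


def write_matrix(bins_path, triplets_path, cm: ContactMatrix) -> None:
    edges = cm.bin_edges()
    with open(bins_path, "w") as fh:
        fh.write(f"#region\t{cm.region}\t{cm.binsize}\t{cm.stage}\n")
        for i in range(cm.n_bins):
            bias = "" if cm.bias is None else f"\t{cm.bias[i]:.10g}"
            fh.write(
                f"{cm.region.chrom}\t{edges[i]}\t{edges[i+1]}\t{i}"
                f"\t{int(cm.mask[i])}{bias}\n"
            )
    with open(triplets_path, "w") as fh:
        iu = np.triu_indices(cm.n_bins)
        for i, j in zip(*iu):
            v = cm.matrix[i, j]
            if v != 0 and np.isfinite(v):
                fh.write(f"{i}\t{j}\t{v:.10g}\n")


def read_matrix(bins_path, triplets_path) -> ContactMatrix:
    from .core import parse_ucsc_region

    mask_rows, bias_rows = [], []
    with open(bins_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 4 or not header[0].startswith("#region"):
            raise ValueError(f"{bins_path}: missing matrix header")
        region = parse_ucsc_region(header[1])
        binsize = int(header[2])
        stage = header[3]
        for line in fh:
            f = line.rstrip("\n").split("\t")
            mask_rows.append(bool(int(f[4])))
            bias_rows.append(float(f[5]) if len(f) > 5 else np.nan)
    n = len(mask_rows)
    m = np.zeros((n, n), dtype=float)
    with open(triplets_path) as fh:
        for line in fh:
            i, j, v = line.split("\t")
            i, j, v = int(i), int(j), float(v)
            m[i, j] = v
            m[j, i] = v
    bias = np.array(bias_rows)
    return ContactMatrix(
        region=region,
        binsize=binsize,
        matrix=m,
        mask=np.array(mask_rows),
        stage=stage,
        bias=None if np.isnan(bias).all() else bias,
    )
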