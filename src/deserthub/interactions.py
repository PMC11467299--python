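"""Significant pairwise contacts under a random-ligation binomial null.

The null model assumes each ligation event joins two fragment ends drawn
independently in proportion to their relative coverage r_i (bin marginal /
total read ends), giving an expected cell probability

    p_ij = 2 * r_i * r_j   (i != j),      p_ii = r_i**2,

which sums to one over unordered pairs.  Each observed count is tested
against the upper tail of Binomial(N = total pairs, p_ij); q-values are
Benjamini-Hochberg over all tested cells (observed >= 1) and calls are
cells with q below the threshold (default 0.1).  No distance-dependent
expectation is used — a documented simplification of the base model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval
from .contacts import ContactMatrix

__all__ = [
    "InteractionCall",
    "expected_probabilities",
    "call_interactions",
    "restrict_to_viewpoint",
    "calls_to_regions",
]


@dataclass(frozen=True)
class InteractionCall:
    bin_i: int
    bin_j: int
    interval_i: GenomicInterval
    interval_j: GenomicInterval
    observed: int
    expected_p: float
    pvalue: float
    qvalue: float

    @property
    def called(self) -> bool:  # kept for table export
        return True


def expected_probabilities(cm: ContactMatrix) -> np.ndarray:
    """Random-ligation cell probabilities from relative bin coverage.

    Returns the full symmetric matrix of p_ij; the sum over unordered
    pairs (upper triangle including the diagonal) is one whenever the
    matrix is non-empty.  Empty bins get zero probability everywhere.
    """
    if cm.stage != "raw":
        raise ValueError("expected probabilities are defined on raw counts")
    m = cm.matrix.astype(float)
    marginal = m.sum(axis=1) + np.diag(m)  # each diagonal pair has 2 ends in i
    total_ends = marginal.sum()
    if total_ends == 0:
        return np.zeros_like(m)
    r = marginal / total_ends
    p = 2.0 * np.outer(r, r)
    np.fill_diagonal(p, r * r)
    return p


def call_interactions(
    cm: ContactMatrix, q_threshold: float = 0.1
) -> list[InteractionCall]:
    """Binomial upper-tail test of every non-empty cell, BH-corrected.

    The p-value is P(X >= observed) for X ~ Binomial(N, p_ij), inclusive
    of the observed count; only unordered cells with observed >= 1 enter
    multiple testing.  Returns calls with q < ``q_threshold`` sorted by
    q-value.
    """
    p_exp = expected_probabilities(cm)
    iu = np.triu_indices(cm.n_bins)
    obs = cm.matrix[iu].astype(np.int64)
    n_total = int(obs.sum())
    tested = obs >= 1
    if n_total == 0 or not tested.any():
        return []
    oi, oj = iu[0][tested], iu[1][tested]
    o = obs[tested]
    pe = p_exp[oi, oj]
    pvals = stats.binom.sf(o - 1, n_total, pe)
    pvals = np.clip(pvals, 0.0, 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    edges = cm.bin_edges()
    calls = []
    for i, j, ob, p_e, p, q in zip(oi, oj, o, pe, pvals, qvals):
        if q < q_threshold:
            calls.append(
                InteractionCall(
                    bin_i=int(i),
                    bin_j=int(j),
                    interval_i=GenomicInterval(
                        cm.region.chrom, int(edges[i]), int(edges[i + 1])
                    ),
                    interval_j=GenomicInterval(
                        cm.region.chrom, int(edges[j]), int(edges[j + 1])
                    ),
                    observed=int(ob),
                    expected_p=float(p_e),
                    pvalue=float(p),
                    qvalue=float(q),
                )
            )
    calls.sort(key=lambda c: (c.qvalue, c.pvalue, c.bin_i, c.bin_j))
    return calls


def interaction_pvalues(
    cm: ContactMatrix, include_empty: bool = False
) -> np.ndarray:
    """Upper-tail p-values of unordered cells, unsorted.

    By default only tested cells (observed >= 1) are returned, matching
    the multiple-testing set of :func:`call_interactions`.  For null-
    calibration checks set ``include_empty=True``: empty cells contribute
    their P(X >= 0) = 1, and the unconditional p-value distribution is
    super-uniform under the random-ligation null, whereas conditioning on
    observed >= 1 removes the p = 1 atom and is anti-conservative near 1
    by construction.
    """
    p_exp = expected_probabilities(cm)
    iu = np.triu_indices(cm.n_bins)
    obs = cm.matrix[iu].astype(np.int64)
    n_total = int(obs.sum())
    if n_total == 0:
        return np.array([])
    tested = np.ones_like(obs, dtype=bool) if include_empty else obs >= 1
    if not tested.any():
        return np.array([])
    pvals = stats.binom.sf(obs[tested] - 1, n_total, p_exp[iu][tested])
    return np.clip(pvals, 0.0, 1.0)


def n_tested(cm: ContactMatrix) -> int:
    iu = np.triu_indices(cm.n_bins)
    return int((cm.matrix[iu] >= 1).sum())


def restrict_to_viewpoint(
    calls: list[InteractionCall], viewpoint: GenomicInterval
) -> list[InteractionCall]:
    """Calls with at least one end overlapping the viewpoint interval."""
    return [
        c
        for c in calls
        if c.interval_i.overlaps(viewpoint) or c.interval_j.overlaps(viewpoint)
    ]


def calls_to_regions(
    calls: list[InteractionCall], viewpoint: GenomicInterval
) -> list[GenomicInterval]:
    """The non-viewpoint ends of viewpoint-restricted calls (contacting
    regions track)."""
    out = []
    for c in restrict_to_viewpoint(calls, viewpoint):
        if c.interval_i.overlaps(viewpoint):
            out.append(c.interval_j)
        else:
            out.append(c.interval_i)
    return sorted(out)
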