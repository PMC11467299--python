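"""Seeded recovery experiments on the synthetic locus.

Each experiment generates data under the default study conditions, runs
the corresponding analysis stage and measures whether the planted
structure is recovered.  They back both the acceptance-style tests and
the reproduction script; all randomness flows from the seeds passed in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import GenomicInterval
from .contacts import (
    balance_matrix,
    bin_pairs,
    filter_bins,
    insulation_and_boundaries,
    interdomain_insulation_matrix,
    subtract_matrices,
)
from .interactions import call_interactions, interaction_pvalues, n_tested
from .simulate import (
    HEART_LOOP_PARTNER,
    PROMOTER_VIEWPOINT,
    default_locus_model,
    simulate_fragment_map,
    simulate_pairs,
)
from .v4c import (
    bin_fragment_counts,
    count_per_fragment,
    scale_profile,
    select_informative_pairs,
    smooth_profile,
    subtract_profiles,
)

__all__ = [
    "V4CSeedResult",
    "v4c_loop_experiment",
    "boundary_recovery_experiment",
    "hcd_experiment",
    "null_fdr_experiment",
    "loop_call_experiment",
    "default_domain_partition",
]


def _partner_bins(profile) -> list[int]:
    lo = profile.bin_of(HEART_LOOP_PARTNER.start)
    hi = profile.bin_of(HEART_LOOP_PARTNER.end - 1)
    return list(range(lo, hi + 1))


@dataclass
class V4CSeedResult:
    conservation_exact: bool
    partner_top1pct_heart: bool
    partner_not_top1pct_limb: bool
    subtraction_max_at_anchor: bool


def _profile_pipeline(pairs, fragmap, viewpoint):
    outside = select_informative_pairs(pairs, viewpoint, fragmap.region)
    counts = count_per_fragment(outside, fragmap)
    raw = bin_fragment_counts(counts, fragmap, viewpoint)
    conservation = bool(
        np.isclose(raw.values.sum(), counts.sum(), rtol=1e-9, atol=1e-6)
    )
    scaled = scale_profile(smooth_profile(raw, 3), 5_000)
    return scaled, conservation


def v4c_loop_experiment(
    seeds: Iterable[int], n_pairs: int = 500_000
) -> list[V4CSeedResult]:
    """Viewpoint-profile recovery of the condition-specific promoter loop.

    Per seed: simulate both conditions (loop boost 8 in heart only), build
    scaled profiles from the promoter viewpoint, and check that (a) binning
    conserves the informative-pair count, (b) the loop-partner bin ranks in
    the top 1% of non-excluded profile values in heart but not in limb,
    and (c) the heart - limb subtraction attains its largest absolute
    value (outside the exclusion zone) at the partner anchor.
    """
    results = []
    for seed in seeds:
        model = default_locus_model(seed=int(seed), n_pairs=n_pairs)
        fragmap = simulate_fragment_map(model.region, 256, seed=int(seed))
        profiles, conservation = {}, True
        for cond in ("heart", "limb"):
            pairs = simulate_pairs(model, cond)
            profiles[cond], ok = _profile_pipeline(
                pairs, fragmap, PROMOTER_VIEWPOINT
            )
            conservation &= ok
        pb = _partner_bins(profiles["heart"])

        def _in_top(profile, fraction=0.01):
            vals = profile.values[~profile.excluded]
            cutoff = np.quantile(vals, 1 - fraction)
            best = max(profile.values[b] for b in pb)
            return bool(best >= cutoff)

        sub = subtract_profiles(profiles["heart"], profiles["limb"])
        absdiff = np.abs(sub.values.copy())
        absdiff[sub.excluded] = -np.inf
        results.append(
            V4CSeedResult(
                conservation_exact=conservation,
                partner_top1pct_heart=_in_top(profiles["heart"]),
                partner_not_top1pct_limb=not _in_top(profiles["limb"]),
                subtraction_max_at_anchor=int(np.argmax(absdiff)) in pb
                and sub.values[int(np.argmax(absdiff))] > 0,
            )
        )
    return results


def boundary_recovery_experiment(
    seeds: Iterable[int],
    n_pairs: int = 1_000_000,
    binsize: int = 5_000,
    condition: str = "limb",
    tolerance_bins: int = 2,
) -> list[bool]:
    """Whether all planted structural boundaries (both TAD edges and the
    sub-domain junction) are recovered within ``tolerance_bins``."""
    out = []
    for seed in seeds:
        model = default_locus_model(seed=int(seed), n_pairs=n_pairs)
        pairs = simulate_pairs(model, condition)
        bal = balance_matrix(filter_bins(bin_pairs(pairs, model.region, binsize)))
        res = insulation_and_boundaries(bal)
        called_bins = [b.bin for b in res.called()]
        planted = [
            bal.bin_of(model.tad.start),
            bal.bin_of(model.subdomains[0].end),
            bal.bin_of(model.tad.end - 1),
        ]
        out.append(
            all(
                any(abs(cb - pb) <= tolerance_bins for cb in called_bins)
                for pb in planted
            )
        )
    return out


def default_domain_partition(model=None) -> list[GenomicInterval]:
    """Flanks, D-dom split at the HCD, and U-dom — the Fig.-style blocks."""
    model = model or default_locus_model()
    d_dom, u_dom = model.subdomains
    hcd = model.hcd
    return [
        GenomicInterval(model.region.chrom, model.region.start, model.tad.start,
                        name="upstream_flank"),
        GenomicInterval(model.region.chrom, d_dom.start, hcd.start, name="D1"),
        GenomicInterval(model.region.chrom, hcd.start, hcd.end, name="HCD"),
        GenomicInterval(model.region.chrom, hcd.end, d_dom.end, name="D2"),
        GenomicInterval(model.region.chrom, u_dom.start, u_dom.end, name="U"),
        GenomicInterval(model.region.chrom, model.tad.end, model.region.end,
                        name="downstream_flank"),
    ]


def hcd_experiment(seed: int = 0, n_pairs: int = 1_000_000) -> dict:
    """Condition-specific dense-domain detection.

    Checks that the inter-domain matrix maximum sits on the HCD diagonal
    entry in heart and elsewhere in limb, and that in the heart - limb
    balanced subtraction the HCD block mean exceeds the 95th percentile of
    equally sized diagonal blocks.
    """
    model = default_locus_model(seed=seed, n_pairs=n_pairs)
    domains = default_domain_partition(model)
    hcd_idx = [d.name for d in domains].index("HCD")
    raw, bal = {}, {}
    for cond in ("heart", "limb"):
        pairs = simulate_pairs(model, cond)
        raw[cond] = filter_bins(bin_pairs(pairs, model.region, 5_000))
        bal[cond] = balance_matrix(raw[cond])
    argmax = {}
    for cond in ("heart", "limb"):
        z = interdomain_insulation_matrix(raw[cond], domains)
        argmax[cond] = np.unravel_index(np.nanargmax(z), z.shape)
    diff = subtract_matrices(bal["heart"], bal["limb"])
    vals = diff.values_with_mask()
    h0, h1 = diff.bin_range(model.hcd)
    width = h1 - h0
    hcd_mean = float(np.nanmean(vals[h0:h1, h0:h1]))
    other = []
    for s in range(0, diff.n_bins - width):
        if abs(s - h0) < width:  # exclude blocks overlapping the HCD itself
            continue
        block = vals[s : s + width, s : s + width]
        if np.isfinite(block).any():
            other.append(float(np.nanmean(block)))
    return {
        "heart_argmax_is_hcd": argmax["heart"] == (hcd_idx, hcd_idx),
        "limb_argmax_is_hcd": argmax["limb"] == (hcd_idx, hcd_idx),
        "hcd_block_mean": hcd_mean,
        "block_p95": float(np.percentile(other, 95)),
    }


def _null_model(seed: int, n_pairs: int):
    """Structure-free uniform-ligation locus (the caller's own null)."""
    return default_locus_model(
        seed=seed, n_pairs=n_pairs, decay_exponent=0.0, domain_boost=1.0,
        hcd_boost=1.0, loops=(), hcd=None,
    )


def null_fdr_experiment(
    seeds: Iterable[int], n_pairs: int = 500_000, binsize: int = 10_000,
    q_threshold: float = 0.1,
) -> list[float]:
    """Fraction of tested cells called at q < threshold per null seed."""
    fracs = []
    for seed in seeds:
        model = _null_model(int(seed), n_pairs)
        raw = bin_pairs(simulate_pairs(model, "limb"), model.region, binsize)
        calls = call_interactions(raw, q_threshold=q_threshold)
        fracs.append(len(calls) / max(n_tested(raw), 1))
    return fracs


def null_ks_pvalue(seed: int = 0, n_pairs: int = 500_000,
                   binsize: int = 10_000) -> float:
    """One-sided KS p-value against anti-conservatism under the null."""
    model = _null_model(seed, n_pairs)
    raw = bin_pairs(simulate_pairs(model, "limb"), model.region, binsize)
    pvals = interaction_pvalues(raw, include_empty=True)
    return float(stats.kstest(pvals, "uniform", alternative="greater").pvalue)


def loop_call_experiment(
    seeds: Iterable[int], n_pairs: int = 500_000, binsize: int = 10_000,
    q_threshold: float = 0.1,
) -> list[bool]:
    """Whether the heart-specific promoter loop cell is called per seed."""
    out = []
    for seed in seeds:
        model = default_locus_model(seed=int(seed), n_pairs=n_pairs)
        raw = bin_pairs(simulate_pairs(model, "heart"), model.region, binsize)
        calls = call_interactions(raw, q_threshold=q_threshold)
        vp_bins = {
            raw.bin_of(PROMOTER_VIEWPOINT.start),
            raw.bin_of(PROMOTER_VIEWPOINT.end - 1),
        }
        partner_bins = {
            raw.bin_of(HEART_LOOP_PARTNER.start),
            raw.bin_of(HEART_LOOP_PARTNER.end - 1),
        }
        out.append(
            any(
                (c.bin_i in vp_bins and c.bin_j in partner_bins)
                or (c.bin_i in partner_bins and c.bin_j in vp_bins)
                for c in calls
            )
        )
    return out
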