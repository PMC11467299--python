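"""Synthetic capture-locus generator.

Emits every input the analysis consumes — valid Hi-C pairs, restriction
fragments, per-tissue peak landscapes, sequence with planted motifs,
conservation and expression tables — with the statistical structure the
pipeline is designed to detect: power-law distance decay, a TAD split into
two loop-anchored sub-domains, a condition-specific high-density contact
sub-domain, anchor-pair loops, tissue-restricted enhancer peaks.

Contacts follow a product-form probability over genomic positions

    P(i, j)  ∝  s_ij^(-alpha) * beta^[same sub-domain] * lambda^[loop pair]
                * hcd_boost^[both ends in the HCD, condition active]

with the distance ``s_ij`` floored at ``decay_floor`` (default 3 kb, one
profile bin) so that the sub-bin regime the real pipeline removes upstream
(self-ligation artefacts) carries no excess mass.  The probability is
evaluated on a fine internal tile grid (default 2 kb, finer than any
analysis bin) and read positions are jittered uniformly within tiles;
every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FragmentMap, GenomicInterval, ScoredInterval
from .io import BedGraph, PairTable

__all__ = [
    "Loop",
    "LocusModel",
    "PlantedEnhancer",
    "PeakLandscapeModel",
    "PeakLandscape",
    "default_locus_model",
    "default_peak_landscape_model",
    "default_tss",
    "simulate_fragment_map",
    "simulate_pairs",
    "simulate_peak_landscape",
    "simulate_sequence_with_motifs",
    "simulate_conservation_track",
    "simulate_expression",
]


def _condition_rng(seed: int, condition: str, salt: int = 0) -> np.random.Generator:
    """Independent, reproducible stream per (seed, condition, stage)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(condition.encode()), salt])
    )


@dataclass(frozen=True)
class Loop:
    """A pairwise contact enrichment between two anchor intervals.

    ``active_in`` restricts the boost to a set of condition labels; ``None``
    means the loop is present in every condition (structural anchor).
    """

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    boost: float = 4.0
    active_in: frozenset[str] | None = None

    def __post_init__(self):
        if self.boost < 1:
            raise ValueError("loop boost must be >= 1")

    def active(self, condition: str) -> bool:
        return self.active_in is None or condition in self.active_in


@dataclass(frozen=True)
class LocusModel:
    """Geometry and contact parameters of the synthetic capture region."""

    region: GenomicInterval
    tad: GenomicInterval
    subdomains: tuple[GenomicInterval, ...]
    hcd: GenomicInterval | None = None
    hcd_active_in: frozenset[str] = frozenset({"heart"})
    hcd_boost: float = 3.0
    loops: tuple[Loop, ...] = ()
    decay_exponent: float = 1.0
    domain_boost: float = 3.0
    n_pairs: int = 500_000
    seed: int = 0
    conditions: tuple[str, ...] = ("heart", "limb")
    low_mapq_rate: float = 0.03
    tile_size: int = 2_000
    decay_floor: int = 3_000

    def __post_init__(self):
        for sd in self.subdomains:
            if not self.tad.contains(sd):
                raise ValueError(f"sub-domain {sd} not inside TAD {self.tad}")
        if self.hcd is not None and not any(
            sd.contains(self.hcd) for sd in self.subdomains
        ):
            raise ValueError("HCD must lie inside one sub-domain")
        for lp in self.loops:
            for anchor in (lp.anchor_a, lp.anchor_b):
                if not self.region.contains(anchor):
                    raise ValueError(f"loop anchor {anchor} outside region")
        if self.decay_exponent < 0:
            raise ValueError("decay exponent must be >= 0")
        if self.domain_boost < 1 or self.hcd_boost < 1:
            raise ValueError("boosts must be >= 1")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")


# Default geometry mirrors the studied mouse locus 1:1 (mm10 chr3): a 3.5 Mb
# capture region, a 1 Mb TAD, a downstream regulatory domain (gene desert)
# and an upstream domain meeting at the target promoter, a 170 kb
# high-density contact domain active only in heart, a structural TAD-corner
# loop and a heart-specific promoter loop.
_REGION = GenomicInterval("chr3", 65_196_078, 68_696_078, name="capture")
_TAD = GenomicInterval("chr3", 66_337_000, 67_337_000, name="tad")
_D_DOM = GenomicInterval("chr3", 66_337_000, 66_980_000, name="D-dom")
_U_DOM = GenomicInterval("chr3", 66_980_000, 67_337_000, name="U-dom")
_HCD = GenomicInterval("chr3", 66_402_500, 66_572_500, name="hcd")
_PROMOTER = GenomicInterval("chr3", 66_975_788, 66_985_788, name="promoter")
# Heart-specific loop partner 120 kb downstream of the promoter anchor:
# close enough that an 8-fold boost dominates the near-viewpoint distance
# decay in a 4C-style profile, the regime the recovery analyses quantify.
_LOOP_PARTNER = GenomicInterval("chr3", 66_850_788, 66_860_788, name="loop_partner")

PROMOTER_VIEWPOINT = _PROMOTER
HEART_LOOP_PARTNER = _LOOP_PARTNER


def default_locus_model(**overrides) -> LocusModel:
    """The study-geometry locus with two conditions ("heart", "limb")."""
    params = dict(
        region=_REGION,
        tad=_TAD,
        subdomains=(_D_DOM, _U_DOM),
        hcd=_HCD,
        hcd_active_in=frozenset({"heart"}),
        hcd_boost=3.0,
        loops=(
            Loop(
                GenomicInterval("chr3", 66_337_000, 66_347_000),
                GenomicInterval("chr3", 67_327_000, 67_337_000),
                boost=4.0,
            ),
            Loop(_PROMOTER, _LOOP_PARTNER, boost=8.0, active_in=frozenset({"heart"})),
        ),
        decay_exponent=1.0,
        domain_boost=3.0,
        n_pairs=500_000,
        seed=0,
    )
    params.update(overrides)
    return LocusModel(**params)


def default_tss() -> list[GenomicInterval]:
    """TSS annotations for the locus: the target gene plus flanking genes."""
    return [
        GenomicInterval("chr3", 66_980_787, 66_980_788, name="Shox2", strand="-"),
        GenomicInterval("chr3", 65_786_000, 65_786_001, name="Veph1", strand="-"),
        GenomicInterval("chr3", 67_490_000, 67_490_001, name="Rsrc1", strand="+"),
        GenomicInterval("chr3", 68_140_000, 68_140_001, name="Mlf1", strand="+"),
    ]


# ---------------------------------------------------------------------------
# Fragment map
# ---------------------------------------------------------------------------


def simulate_fragment_map(
    region: GenomicInterval, mean_fragment_len: int = 256, seed: int = 0
) -> FragmentMap:
    """Emulate a 4-cutter digest: geometric inter-cut spacing.

    Cut spacings are i.i.d. geometric with the stated mean, so the empirical
    mean fragment length converges to ``mean_fragment_len``; the fragments
    tile the region exactly (the last fragment is truncated at the region
    end).
    """
    if mean_fragment_len < 50:
        raise ValueError("mean_fragment_len must be >= 50")
    length = region.length()
    if length < 2 * mean_fragment_len:
        raise ValueError(
            f"region of {length} bp too short for mean fragment "
            f"{mean_fragment_len} bp"
        )
    rng = np.random.default_rng(seed)
    n_est = int(length / mean_fragment_len * 1.5) + 16
    spacings = rng.geometric(1.0 / mean_fragment_len, size=n_est)
    while spacings.sum() < length:
        spacings = np.concatenate(
            [spacings, rng.geometric(1.0 / mean_fragment_len, size=n_est)]
        )
    cuts = region.start + np.cumsum(spacings)
    cuts = cuts[cuts < region.end]
    boundaries = np.concatenate([[region.start], cuts, [region.end]])
    boundaries = np.unique(boundaries)
    return FragmentMap(region.chrom, boundaries)


# ---------------------------------------------------------------------------
# Contact pairs
# ---------------------------------------------------------------------------


def _tile_edges(model: LocusModel) -> np.ndarray:
    edges = np.arange(model.region.start, model.region.end, model.tile_size)
    return np.append(edges, model.region.end)


def contact_cell_weights(
    model: LocusModel, condition: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unnormalised contact weights over unordered tile pairs.

    Returns ``(i, j, weights, tile_edges)`` with ``i <= j`` tile indices.
    Exposed so tests can compare sampled counts against the exact model.
    """
    edges = _tile_edges(model)
    mids = (edges[:-1] + edges[1:]) / 2.0
    n = mids.size
    ii, jj = np.triu_indices(n)
    dist = np.maximum(mids[jj] - mids[ii], float(model.decay_floor))
    if model.decay_exponent == 0:
        w = np.ones_like(dist)
    else:
        w = dist ** (-model.decay_exponent)

    def _inside(iv: GenomicInterval) -> np.ndarray:
        return (mids >= iv.start) & (mids < iv.end)

    for sd in model.subdomains:
        m = _inside(sd)
        w[m[ii] & m[jj]] *= model.domain_boost
    if model.hcd is not None and condition in model.hcd_active_in:
        m = _inside(model.hcd)
        w[m[ii] & m[jj]] *= model.hcd_boost
    for lp in model.loops:
        if not lp.active(condition):
            continue
        a, b = _inside(lp.anchor_a), _inside(lp.anchor_b)
        w[(a[ii] & b[jj]) | (b[ii] & a[jj])] *= lp.boost
    return ii, jj, w, edges


def simulate_pairs(model: LocusModel, condition: str) -> PairTable:
    """Draw ``model.n_pairs`` valid read pairs for one condition.

    Deterministic given ``(model.seed, condition)``; independent conditions
    use independent RNG streams.  A ``low_mapq_rate`` fraction of mate MAPQs
    falls below 30 (uniform on [0, 30)), the rest on [30, 61).
    """
    rng = _condition_rng(model.seed, condition)
    if model.n_pairs == 0:
        return PairTable(model.region.chrom, [], [], [], [])
    ii, jj, w, edges = contact_cell_weights(model, condition)
    p = w / w.sum()
    counts = rng.multinomial(model.n_pairs, p)
    nz = counts > 0
    reps = counts[nz]
    ti = np.repeat(ii[nz], reps)
    tj = np.repeat(jj[nz], reps)
    widths = np.diff(edges)
    pos1 = edges[ti] + rng.integers(0, widths[ti])
    pos2 = edges[tj] + rng.integers(0, widths[tj])
    # randomise mate order so neither column is systematically upstream
    swap = rng.random(pos1.size) < 0.5
    pos1, pos2 = np.where(swap, pos2, pos1), np.where(swap, pos1, pos2)
    perm = rng.permutation(pos1.size)
    pos1, pos2 = pos1[perm], pos2[perm]

    def _mapqs(size: int) -> np.ndarray:
        low = rng.random(size) < model.low_mapq_rate
        return np.where(
            low, rng.integers(0, 30, size=size), rng.integers(30, 61, size=size)
        ).astype(np.int32)

    return PairTable(
        model.region.chrom, pos1, pos2, _mapqs(pos1.size), _mapqs(pos1.size)
    )


# ---------------------------------------------------------------------------
# Peak landscape
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedEnhancer:
    interval: GenomicInterval
    active_in: frozenset[str]
    rpkm: float


@dataclass(frozen=True)
class PeakLandscapeModel:
    """Tissue-by-stage H3K27ac peak landscape with planted enhancers."""

    region: GenomicInterval
    combos: tuple[str, ...]
    planted: tuple[PlantedEnhancer, ...]
    true_q_range: tuple[float, float] = (1e-8, 1e-3)
    decoy_q_range: tuple[float, float] = (1e-4, 0.099)
    decoy_rate: float = 0.0  # expected decoy peaks per combo
    edge_jitter: int = 50
    seed: int = 0

    def __post_init__(self):
        for enh in self.planted:
            if not self.region.contains(enh.interval):
                raise ValueError(f"planted enhancer {enh.interval} outside region")
            for c in enh.active_in:
                if c not in self.combos:
                    raise ValueError(f"unknown combo {c!r} for {enh.interval}")
        if self.decoy_rate < 0:
            raise ValueError("decoy_rate must be >= 0")


_TISSUES = (
    "forebrain",
    "midbrain",
    "hindbrain",
    "neural-tube",
    "heart",
    "limb",
    "facial-prominence",
    "liver",
    "lung",
    "kidney",
    "stomach",
)
_STAGES = ("E10.5", "E11.5", "E12.5", "E13.5", "E14.5", "E15.5")


def encode_style_combos() -> tuple[str, ...]:
    """The 66 tissue-by-stage labels of a developmental ChIP-seq compendium."""
    return tuple(f"{t}_{s}" for t in _TISSUES for s in _STAGES)


def default_peak_landscape_model(
    n_enhancers: int = 16, decoy_rate: float = 0.0, seed: int = 0
) -> PeakLandscapeModel:
    """Planted enhancers spread over the TAD, each active in 1-5 combos."""
    combos = encode_style_combos()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE14A]))
    # enhancers spaced >= 10 kb so stitching (1 kb) never merges two of them
    slots = np.linspace(_TAD.start + 20_000, _TAD.end - 20_000, n_enhancers)
    planted = []
    for k, center in enumerate(slots):
        half = int(rng.integers(400, 1_500))
        iv = GenomicInterval(
            _TAD.chrom, int(center) - half, int(center) + half, name=f"enh_{k}"
        )
        n_active = int(rng.integers(1, 6))
        active = frozenset(rng.choice(combos, size=n_active, replace=False))
        planted.append(PlantedEnhancer(iv, active, float(rng.uniform(5, 50))))
    # promoters carry the same acetylation mark: plant one element at the
    # target-gene TSS so the TSS-proximity filter has real work to do
    planted.append(
        PlantedEnhancer(
            GenomicInterval(_TAD.chrom, 66_980_000, 66_981_500, name="promoter_peak"),
            frozenset({"heart_E11.5", "limb_E11.5"}),
            30.0,
        )
    )
    return PeakLandscapeModel(
        region=_REGION,
        combos=combos,
        planted=tuple(planted),
        decoy_rate=decoy_rate,
        seed=seed,
    )


@dataclass
class PeakLandscape:
    """Simulated per-combo peak calls and signal tracks plus the truth."""

    model: PeakLandscapeModel
    peaks: dict[str, list[ScoredInterval]]
    signal: dict[str, BedGraph]


def _log_uniform(rng, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def simulate_peak_landscape(model: PeakLandscapeModel) -> PeakLandscape:
    """Emit peaks and signal per combo.

    Planted enhancers emit a peak (low q, signal = configured RPKM within a
    few percent) in exactly their active combos; decoy peaks appear at
    Poisson(``decoy_rate``) random positions per combo.  With
    ``decoy_rate=0`` every emitted peak overlaps a planted enhancer.
    """
    peaks: dict[str, list[ScoredInterval]] = {c: [] for c in model.combos}
    sig_iv: dict[str, list[tuple[int, int, float]]] = {c: [] for c in model.combos}
    for enh in model.planted:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [model.seed, zlib.crc32(str(enh.interval).encode())]
            )
        )
        for combo in model.combos:
            if combo not in enh.active_in:
                continue
            j1 = int(rng.integers(-model.edge_jitter, model.edge_jitter + 1))
            j2 = int(rng.integers(-model.edge_jitter, model.edge_jitter + 1))
            start = max(model.region.start, enh.interval.start + j1)
            end = min(model.region.end, enh.interval.end + j2)
            q = _log_uniform(rng, *model.true_q_range)
            level = enh.rpkm * float(rng.uniform(0.97, 1.03))
            peaks[combo].append(
                ScoredInterval(
                    enh.interval.chrom,
                    start,
                    end,
                    name=enh.interval.name,
                    score=-np.log10(q),
                    qvalue=q,
                    signal=level,
                )
            )
            sig_iv[combo].append((enh.interval.start, enh.interval.end, level))
    if model.decoy_rate > 0:
        rng = np.random.default_rng(np.random.SeedSequence([model.seed, 0xDEC0]))
        for combo in model.combos:
            for _ in range(rng.poisson(model.decoy_rate)):
                width = int(rng.integers(600, 2_000))
                start = int(
                    rng.integers(model.region.start, model.region.end - width)
                )
                q = _log_uniform(rng, *model.decoy_q_range)
                peaks[combo].append(
                    ScoredInterval(
                        model.region.chrom,
                        start,
                        start + width,
                        name="decoy",
                        score=-np.log10(q),
                        qvalue=q,
                        signal=float(rng.uniform(1, 5)),
                    )
                )
    signal = {}
    for combo in model.combos:
        rows = sorted(sig_iv[combo])
        signal[combo] = BedGraph(
            model.region.chrom,
            [r[0] for r in rows],
            [r[1] for r in rows],
            [r[2] for r in rows],
        )
    return PeakLandscape(model=model, peaks=peaks, signal=signal)


# ---------------------------------------------------------------------------
# Sequence, conservation, expression
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = np.array(list("ACGT"))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def consensus_of(matrix: np.ndarray) -> str:
    """Highest-probability base per column of a 4 x W matrix (ACGT rows)."""
    return "".join(_BASES[np.argmax(np.asarray(matrix), axis=0)])


def simulate_sequence_with_motifs(
    length: int,
    gc: float = 0.5,
    plants: Sequence[tuple] = (),
    seed: int = 0,
    name: str = "synthetic",
) -> tuple[str, list[dict]]:
    """Random sequence at a target GC content with planted motif words.

    ``plants`` holds ``(pwm_or_matrix, position, strand)`` triples; the
    motif's consensus word (reverse-complemented on '-') is written verbatim
    at the recorded offset.  Returns the sequence and a truth table of the
    planted occurrences.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(_BASES, size=length, p=probs)
    truth = []
    for pwm, position, strand in plants:
        matrix = getattr(pwm, "matrix", pwm)
        motif_id = getattr(pwm, "motif_id", "motif")
        word = consensus_of(matrix)
        if strand == "-":
            word = _revcomp(word)
        elif strand != "+":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        if position < 0 or position + len(word) > length:
            raise ValueError("planted motif outside sequence")
        seq[position : position + len(word)] = list(word)
        truth.append(
            {
                "motif_id": motif_id,
                "start": position,
                "end": position + len(word),
                "strand": strand,
                "word": word,
            }
        )
    return "".join(seq), truth


def simulate_conservation_track(
    chrom: str,
    region: GenomicInterval,
    conserved: Iterable[GenomicInterval],
    base_level: float = 0.05,
    boost: float = 2.0,
) -> BedGraph:
    """Step track at ``base_level`` everywhere, ``boost`` over ``conserved``."""
    from .core import merge_intervals

    blocks = merge_intervals(list(conserved), 0)
    starts, ends, values = [], [], []
    cursor = region.start
    for blk in blocks:
        if blk.start > cursor:
            starts.append(cursor)
            ends.append(blk.start)
            values.append(base_level)
        starts.append(blk.start)
        ends.append(blk.end)
        values.append(boost)
        cursor = blk.end
    if cursor < region.end:
        starts.append(cursor)
        ends.append(region.end)
        values.append(base_level)
    return BedGraph(chrom, starts, ends, values)


def simulate_expression(
    tfs: Sequence[str],
    expressed: Iterable[str],
    n_replicates: int = 3,
    expressed_fpkm: tuple[float, float] = (2.0, 40.0),
    silent_fpkm: tuple[float, float] = (0.0, 1.8),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-replicate FPKM table; genes in ``expressed`` have mean >= 2."""
    expressed = set(expressed)
    rng = np.random.default_rng(seed)
    rows = {}
    for tf in tfs:
        lo, hi = expressed_fpkm if tf in expressed else silent_fpkm
        rows[tf] = rng.uniform(lo, hi, size=n_replicates)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"rep{i+1}" for i in range(n_replicates)]
    ).rename_axis("gene_id")
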