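# Methods

This package re-implements, at desk scale, the computational layer used to
dissect a developmental gene-desert regulatory landscape: virtual-4C
profile extraction from capture Hi-C valid pairs, contact-map filtering /
balancing / insulation / boundary calling, binomial interaction calling,
multi-tissue enhancer cataloguing, and expression-filtered PWM motif
scanning.  Because the original sequencing data are not required, a
synthetic locus generator produces every input with the statistical
structure those analyses are designed to detect, together with truth
tables, so every stage is testable end to end.

## The synthetic locus

The generator emulates a 3.5 Mb capture window on mouse chr3
(65,196,078–68,696,078) containing a 1 Mb TAD (66,337,000–67,337,000)
split at the target-gene promoter (viewpoint 66,975,788–66,985,788, 10 kb)
into a downstream regulatory domain ("D-dom", 643 kb, the gene desert) and
an upstream domain ("U-dom", 357 kb).  The TAD edges and the promoter
coordinate are both fixed by the published locus, which leaves the
downstream domain at 643 kb.  Inside D-dom sits a 170 kb high-density
contact domain (HCD, 66,402,500–66,572,500) active only in the "heart"
condition.  Two loops are planted by default: a structural TAD-corner
anchor pair (boost 4, all conditions) and a heart-specific promoter loop
whose partner anchor lies 120 kb downstream of the viewpoint (boost 8).

Contact pairs follow a product-form probability over genomic positions:

    P(i, j) ∝ s_ij^(−α) · β^[same sub-domain] · λ^[loop anchor pair]
              · h^[both ends in HCD, condition active]

with defaults α = 1 (the canonical intra-chromosomal decay slope at the
10 kb–1 Mb scale), β = 3, λ ∈ {4, 8}, h = 3, and the distance floored at
3 kb (one profile bin) so the sub-bin regime that the upstream processing
of real data removes carries no excess mass.  α = 0 is allowed and yields
the ends-independent uniform-ligation model — exactly the null of the
binomial interaction caller — which is what the caller's calibration
experiments use.  The probability is evaluated on a 2 kb internal tile
grid (finer than any analysis bin) with positions jittered uniformly
inside tiles; sampling is one multinomial draw per condition, so every
generator is a pure function of (parameters, seed) and conditions use
independent, reproducibly derived RNG streams.

The loop-partner placement is a deliberate signal-to-noise choice: in a
4C-style profile the near-viewpoint distance decay scales as 1/s, so an
8-fold boosted partner is only separable from the near field (top-1% rank
at 5×10^5 pairs) when the anchor separation stays below roughly
λ × (viewpoint + exclusion) ≈ 200 kb.  120 kb puts the planted signal
comfortably in the detectable regime while remaining a realistic sub-TAD
promoter–enhancer distance.

What the generator does **not** emulate: read-level sequences and mapping
artefacts, ligation-junction chimeras, per-bin technical coverage bias
(capture-probe efficiency, mappability), trans contacts, polymer-physics
contact correlations, and replicate structure.  Passing tests therefore
demonstrate that the analysis recovers the planted statistical signatures,
not that it is robust to technical biases absent from the model.

## Virtual 4C

Pairs are kept when both MAPQs are ≥ 30 and exactly one read position
falls inside the viewpoint ("inside" means the read's mapped position lies
within the viewpoint interval — the simplest total criterion).  Outside
reads are counted per restriction fragment, fragment counts are spread
into 3 kb bins proportionally to the fragment/bin overlap (uniform
read-density assumption within a fragment; the binned total equals the
informative-pair count exactly), smoothed by a centred moving average
(window 3 bins by default, shrinking symmetrically at the edges), and
scaled so that the bins outside the viewpoint ± 5 kb sum to 10^6 —
counts-per-million over the non-excluded region, which makes cross-tissue
subtraction meaningful.  Subtraction is a plain difference of scaled
profiles.

## Contact maps, balancing, insulation

Raw matrices bin pairs at 5 kb.  Bins are masked (never zeroed) when they
have fewer than 10 non-zero cells or a log10 marginal more than 5 MADs
below the median of non-empty bins.  Balancing is iterative correction
with the first two diagonals ignored, tolerance 1e−5 on the variance of
the rescaled marginals, at most 200 iterations, and a √-damped update;
the returned bias vector satisfies balanced_ij = bias_i · raw_ij · bias_j
and retained marginals equal one.

Insulation uses diamond windows of {50, 100, 150} kb: the mean balanced
value in the w×w diamond upstream×downstream of each bin, z-scored per
window; the TAD-separation score averages the z-scores.  Candidate
boundaries are local minima at least 0.01 (z units) below both flanking
maxima.  Each candidate's p-value is a one-sided Wilcoxon rank-sum test
of the pooled boundary-diamond cells against the pooled diamond cells at
the two flanking maxima (only windows that fit entirely inside the matrix
participate — truncated edge diamonds would otherwise leak cross-junction
cells into the sample).  Boundaries are classed strong (p < 0.01) or weak
(0.01 ≤ p < 0.05); Benjamini–Hochberg q-values across candidates are
reported alongside the raw p. Because candidates are selected as minima
of the same data the test then scores, the p-values are enrichment scores
rather than calibrated error rates — the planted-boundary recovery tests
pin the behaviour that matters.

The inter-domain matrix divides each domain-block's mean contact by the
distance-expected mean (per-diagonal average) and z-scores the entries.
It is computed on the mask-filtered **raw** matrix rather than the
balanced one: the per-diagonal expectation already removes the distance
effect, the generator has no technical coverage bias for balancing to
correct, and iterative correction — by equalising marginals — cancels
most of the very density contrast the matrix is meant to display (a
dense block inflates its bins' marginals, and the bias product divides
the block back down).  On balanced input the long-range intra-domain
blocks dominate in every condition and the condition-specific dense
domain is undetectable by ranking.

## Interaction calling

The random-ligation null assigns cell (i, j) probability 2·r_i·r_j
(r_i² on the diagonal), where r_i is bin i's share of read ends; these
sum to one over unordered cells.  Observed counts are tested against the
upper tail of Binomial(N, p_ij) inclusive of the observed value; only
cells with at least one observed pair enter BH correction, and calls are
q < 0.1 (the published threshold).  There is no distance-dependent
expectation — a known simplification of the base model, which is why
calibration experiments run on the α = 0 locus where the null is exact.
On the synthetic locus, calling uses 10 kb bins so that one 10 kb anchor
pair maps to essentially one cell (the original genome-wide analysis used
1 kb; the resolution is configurable).

## Enhancer catalog

Peaks from all tissue×stage combinations (66 by default, an 11-tissue ×
6-stage grid) are merged and stitched when within 1 kb.  Each region is
annotated per combination with the lowest overlapping peak q-value —
missing stays missing (NaN), never imputed, so heatmaps distinguish "no
peak" from "weak peak".  TSS proximity is window overlap with TSS ± 2.5 kb
(the closest testable reading of the proximity rule); strong-enhancer
chromatin-state intersection requires ≥ 1 bp overlap.  Signal is
log2(RPKM + 1) — the pseudocount of 1 is this package's choice.  Tier
membership is overlap with each stringency tier's peak set; nested peak
sets give nested tiers.

## Motif scanning

PWMs are kept when their factor's mean FPKM across RNA-seq replicates is
≥ 2 (inclusive).  Log-odds use a pseudocount of 0.1 distributed
proportionally to the background; the background is the 0-order
GC-matched composition of the scanned sequence itself (configurable),
which is strand-symmetric, so one exact null distribution serves both
strands.  P-values are exact: the null distribution of the total score is
built by dynamic programming over scores discretised at 10^−3 bits, and
scanning scores windows on the same integer grid, so DP p-values agree
with full 4^W enumeration up to that discretisation.  Hits at p ≤ 10^−4
(default) are reported on both strands; a hit fully contained in a
longer, at-least-as-significant hit of the same factor is pruned (the
per-locus generalisation of dropping motifs whose genome-wide matches are
subsumed by longer collection members).  Hit conservation is the
arithmetic per-base mean of the conservation track, uncovered bases
counting zero.

## Problem sizes and numerical conventions

Recovery experiments run 10 seeds each at the study-condition depths:
5×10^5 pairs for viewpoint-profile and interaction experiments, 10^6 for
boundary and dense-domain experiments.  The whole test suite and the
reproduction script each complete in well under a minute of compute per
stage on a single core.  Throughout: coordinates are 0-based half-open
(printed `chr:start-end` strings are taken as half-open spans — printed
sizes round identically at printed precision under either convention);
chromosome names match by exact string equality; strand is carried but
ignored outside motif scanning; masked matrix cells propagate as missing,
never zero; a position on a restriction cut site belongs to the fragment
starting there.

## Known limitations

- The binomial caller is anti-conservative on decaying (α > 0) contact
  data at short range, by construction; it is calibrated only under its
  own uniform-ligation null.
- Boundary p-values inherit selection bias (tested at detected minima).
- The product-form contact model has no polymer correlations; balanced
  maps of it differ from balanced maps of real capture Hi-C in how dense
  blocks survive correction (see the inter-domain matrix note above).
- The motif module reports per-window exact p-values, not genome-scale
  q-values, matching its intended per-locus use.
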