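# deserthub

Desk-scale analysis of a gene-desert regulatory landscape: how a gene-free
stretch of DNA downstream of a developmental gene folds into regulatory
domains, which distal elements behave like enhancers, and which
transcription-factor motifs they contain.

Gene deserts (> 500 kb without genes) often harbour the long-range
enhancers of neighbouring developmental genes.  Dissecting one
computationally takes a stack of genomics operations that usually live in
a dozen separate tools: extracting one-vs-all promoter interaction
profiles (virtual 4C) from capture Hi-C read pairs, balancing contact
matrices and calling domain boundaries from insulation scores, testing
pairwise contacts against a random-ligation null, merging H3K27ac peak
calls from dozens of tissue×stage combinations into an annotated enhancer
catalog, and scanning candidate enhancers for motifs of expressed
transcription factors.  `deserthub` implements that stack as one tested
Python package, plus a synthetic locus generator that plants every
structure the analyses are meant to find — a TAD with two sub-domains, a
condition-specific high-density contact domain, loop anchors, power-law
distance decay, tissue-restricted enhancer peaks, motifs with known
positions — so the whole pipeline runs and is validated without any
sequencing data.

## The statistics at the core

- **Virtual 4C** — keep pairs with MAPQ ≥ 30 and exactly one read in the
  viewpoint; count outside reads per restriction fragment; spread counts
  into 3 kb bins ∝ overlap; smooth (moving average); scale to
  counts-per-million outside the viewpoint ± 5 kb; subtract conditions.
- **Matrix balancing** — iterative correction with MAD-based bin masking
  (`mad-max 5, min-nnz 10, ignore-diags 2, tol 1e-5, max-iters 200`),
  returning biases with `balanced_ij = b_i · raw_ij · b_j`.
- **Insulation / boundaries** — diamond insulation at {50, 100, 150} kb,
  z-scored per window and averaged into a TAD-separation score; local
  minima tested against their flanks by one-sided Wilcoxon rank-sum,
  classed strong (p < 0.01) / weak (p < 0.05), BH-corrected.
- **Interaction calling** — random-ligation null `p_ij = 2 r_i r_j` with
  `r_i = marginal_i / total ends`; upper-tail Binomial(N, p_ij) p-values,
  BH over observed cells, calls at q < 0.1.
- **Enhancer catalog** — merge peaks across 66 tissue×stage combos,
  stitch within 1 kb, annotate each region per combo with the lowest
  overlapping q-value and log2(RPKM+1) signal, drop regions overlapping
  TSS ± 2.5 kb, intersect chromatin-state strong enhancers, report
  stringency tiers.
- **Motif scanning** — PWMs of factors with mean FPKM ≥ 2, log-odds
  against a GC-matched 0-order background, *exact* p-values via dynamic
  programming over discretised scores (agrees with 4^W enumeration),
  hits at p ≤ 1e-4 on both strands, nested same-factor hits pruned,
  per-hit mean conservation.

## Worked example

Find the condition-specific promoter contact in a simulated locus where a
heart-only loop (8-fold boost) is planted 120 kb downstream of the
viewpoint:

```python
import numpy as np
from deserthub.simulate import (default_locus_model, simulate_pairs,
                                simulate_fragment_map, PROMOTER_VIEWPOINT,
                                HEART_LOOP_PARTNER)
from deserthub.v4c import viewpoint_profile, subtract_profiles

model = default_locus_model(seed=0, n_pairs=500_000)
fragmap = simulate_fragment_map(model.region, 256, seed=0)
profiles = {
    cond: viewpoint_profile(simulate_pairs(model, cond), fragmap,
                            PROMOTER_VIEWPOINT)
    for cond in ("heart", "limb")
}
sub = subtract_profiles(profiles["heart"], profiles["limb"])
diff = np.abs(sub.values)
diff[sub.excluded] = -np.inf          # ignore the viewpoint zone
top = int(np.argmax(diff))
print(f"strongest differential bin: {sub.bin_interval(top)}")
print(f"planted loop partner:       {HEART_LOOP_PARTNER}")
print(f"heart - limb difference:    {sub.values[top]:+.0f} CPM")
```

prints

```
strongest differential bin: chr3:66852078-66855078
planted loop partner:       chr3:66850788-66860788
heart - limb difference:    +13361 CPM
```

The strongest heart-vs-limb differential contact of the promoter is the
3 kb bin inside the planted anchor, enriched in heart by ~13,000
counts-per-million — the pipeline recovers the planted loop from raw
simulated read pairs.

The same stages are scriptable from the shell:

```bash
desert-hub run --out demo_run --seed 1          # full pipeline + manifest
desert-hub v4c --pairs demo_run/pairs_heart.bedpe \
    --fragments demo_run/fragments.bed \
    --viewpoint chr3:66975788-66985788 --out heart_v4c.bedgraph
```

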