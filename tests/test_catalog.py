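"""Enhancer-catalog construction: stitching, annotation, filters, tiers."""

import numpy as np
import pytest

from deserthub.core import GenomicInterval, ScoredInterval
from deserthub.catalog import (
    annotate_min_q,
    build_catalog,
    build_master_list,
    catalog_to_frame,
    filter_tss_proximal,
    intersect_strong_enhancers,
    quantify_log2_rpkm,
    tier_report,
)


def _peak(start, end, q=0.01, chrom="chr3"):
    return ScoredInterval(chrom, start, end, qvalue=q, score=-np.log10(q))


class TestMasterList:
    def test_cross_combo_stitching(self):
        """Peaks from different combos within 1 kb stitch into one region."""
        peaks = {"A": [_peak(100, 200)], "B": [_peak(900, 1_000)]}
        assert build_master_list(peaks) == [GenomicInterval("chr3", 100, 1_000)]

    def test_distant_peaks_stay_separate(self):
        peaks = {"A": [_peak(100, 200), _peak(1_300, 1_400)]}
        assert len(build_master_list(peaks)) == 2

    def test_idempotent_and_order_invariant(self):
        peaks = {
            "A": [_peak(5_000, 5_400), _peak(100, 200)],
            "B": [_peak(700, 1_000), _peak(5_600, 5_900)],
        }
        master = build_master_list(peaks)
        rebuilt = build_master_list({"x": [_peak(r.start, r.end) for r in master]})
        assert rebuilt == master
        reordered = build_master_list(
            {"B": list(reversed(peaks["B"])), "A": peaks["A"]}
        )
        assert reordered == master


class TestAnnotateMinQ:
    def test_lowest_q_wins(self):
        regions = [GenomicInterval("chr3", 0, 1_000)]
        peaks = {"A": [_peak(10, 200, q=0.01), _peak(300, 600, q=0.001)]}
        out = annotate_min_q(regions, peaks)
        assert out[0].min_q["A"] == pytest.approx(0.001)

    def test_no_overlap_is_missing_not_one(self):
        regions = [GenomicInterval("chr3", 0, 1_000)]
        out = annotate_min_q(regions, {"A": [_peak(5_000, 6_000)]})
        assert "A" not in out[0].min_q
        frame = catalog_to_frame(out, ["A"])
        assert np.isnan(frame.loc[0, "q_A"])

    def test_matches_exhaustive_scan(self, rng):
        regions = [
            GenomicInterval("chr3", int(s), int(s) + 500)
            for s in rng.integers(0, 20_000, 15)
        ]
        peaks = {
            "A": [
                _peak(int(s), int(s) + 300, q=float(q))
                for s, q in zip(
                    rng.integers(0, 20_000, 40), rng.uniform(1e-6, 0.1, 40)
                )
            ]
        }
        out = annotate_min_q(regions, peaks)
        for reg in out:
            qs = [
                p.qvalue for p in peaks["A"] if p.overlaps(reg.interval)
            ]
            if qs:
                assert reg.min_q["A"] == pytest.approx(min(qs))
            else:
                assert "A" not in reg.min_q


class TestTssFilter:
    def _regions(self, *spans):
        return annotate_min_q(
            [GenomicInterval("chr3", s, e) for s, e in spans], {}
        )

    def test_boundary_distance(self):
        """Edge distance 2,501 bp is distal; containment is proximal."""
        tss = [GenomicInterval("chr3", 10_000, 10_001)]
        far = self._regions((5_000, 7_500))      # nearest base 7499, gap 2501
        distal, proximal = filter_tss_proximal(far, tss)
        assert len(distal) == 1 and not proximal
        near = self._regions((5_000, 7_501))     # nearest base 7500, gap 2500
        distal, proximal = filter_tss_proximal(near, tss)
        assert len(proximal) == 1 and not distal
        containing = self._regions((9_000, 11_000))
        distal, proximal = filter_tss_proximal(containing, tss)
        assert len(proximal) == 1

    def test_matches_window_overlap_oracle(self, rng):
        tss = [
            GenomicInterval("chr3", int(p), int(p) + 1)
            for p in rng.integers(0, 100_000, 10)
        ]
        regions = self._regions(
            *[(int(s), int(s) + 800) for s in rng.integers(0, 100_000, 50)]
        )
        distal, proximal = filter_tss_proximal(regions, tss, radius=2_500)
        for reg in regions:
            hit = any(
                reg.interval.start < t.start + 1 + 2_500
                and t.start - 2_500 < reg.interval.end
                for t in tss
            )
            assert reg.tss_distal == (not hit)
        assert len(distal) + len(proximal) == len(regions)


class TestChromHmmIntersection:
    def test_touch_is_not_overlap_containment_is(self):
        regions = annotate_min_q([GenomicInterval("chr3", 1_000, 2_000)], {})
        touching = [GenomicInterval("chr3", 2_000, 3_000)]
        intersect_strong_enhancers(regions, touching)
        assert regions[0].chromhmm_strong is False
        contained = [GenomicInterval("chr3", 1_200, 1_300)]
        intersect_strong_enhancers(regions, contained)
        assert regions[0].chromhmm_strong is True

    def test_matches_per_base_oracle(self, rng):
        regions = annotate_min_q(
            [GenomicInterval("chr3", int(s), int(s) + 400)
             for s in rng.integers(0, 30_000, 30)],
            {},
        )
        segs = [
            GenomicInterval("chr3", int(s), int(s) + 250)
            for s in rng.integers(0, 30_000, 20)
        ]
        mask = np.zeros(40_000, dtype=bool)
        for s in segs:
            mask[s.start : s.end] = True
        intersect_strong_enhancers(regions, segs)
        for reg in regions:
            assert reg.chromhmm_strong == bool(
                mask[reg.interval.start : reg.interval.end].any()
            )


class TestRpkm:
    def test_worked_example(self):
        """10 reads over 2 kb in a 1M-read library: RPKM 5, log2(6)=2.585."""
        assert quantify_log2_rpkm(10, 2_000, 1_000_000) == pytest.approx(
            2.585, abs=1e-3
        )

    def test_zero_reads_floors_at_zero(self):
        assert quantify_log2_rpkm(0, 2_000, 1_000_000) == 0.0

    def test_depth_scale_invariance(self):
        a = quantify_log2_rpkm(10, 2_000, 1_000_000)
        b = quantify_log2_rpkm(20, 2_000, 2_000_000)
        assert a == pytest.approx(b)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            quantify_log2_rpkm(5, 0, 1_000_000)


class TestTiers:
    def test_nested_tiers_give_nested_counts(self):
        regions = annotate_min_q(
            [GenomicInterval("chr3", 0, 500), GenomicInterval("chr3", 2_000, 2_500),
             GenomicInterval("chr3", 9_000, 9_500)],
            {},
        )
        loose = [_peak(0, 400), _peak(2_100, 2_300), _peak(9_100, 9_200)]
        mid = loose[:2]
        strict = loose[:1]
        counts = tier_report(
            regions, {"p<1e-5": strict, "q<0.05": mid, "p<0.001": loose}
        )
        assert counts == {"p<1e-5": 1, "q<0.05": 2, "p<0.001": 3}
        member_counts = sorted(len(r.tiers) for r in regions)
        assert member_counts == [1, 2, 3]

    def test_empty_strict_tier(self):
        regions = annotate_min_q([GenomicInterval("chr3", 0, 500)], {})
        assert tier_report(regions, {"strict": []}) == {"strict": 0}


class TestPlantedRecovery:
    def test_distal_regions_match_planted_one_to_one(self):
        """Zero decoys: distal stitched regions correspond exactly to the
        planted enhancers that are not TSS-proximal."""
        from deserthub.simulate import (
            default_peak_landscape_model,
            default_tss,
            simulate_peak_landscape,
        )

        model = default_peak_landscape_model(decoy_rate=0.0, seed=9)
        landscape = simulate_peak_landscape(model)
        tss = default_tss()
        regions = build_catalog(landscape.peaks, tss,
                                signal_by_combo=landscape.signal)
        distal = [r for r in regions if r.tss_distal]
        windows = [t.pad(2_500) for t in tss]
        expected = [
            e for e in model.planted
            if not any(e.interval.overlaps(w) for w in windows)
        ]
        assert len(distal) == len(expected)
        for reg in distal:
            hits = [e for e in expected if e.interval.overlaps(reg.interval)]
            assert len(hits) == 1

    def test_heatmap_export_is_lossless(self):
        from deserthub.simulate import (
            default_peak_landscape_model,
            default_tss,
            simulate_peak_landscape,
        )

        model = default_peak_landscape_model(decoy_rate=0.0, seed=9)
        landscape = simulate_peak_landscape(model)
        regions = build_catalog(landscape.peaks, default_tss(),
                                signal_by_combo=landscape.signal)
        frame = catalog_to_frame(regions, model.combos)
        for idx, reg in enumerate(regions):
            for combo in model.combos:
                cell = frame.loc[idx, f"q_{combo}"]
                if combo in reg.min_q:
                    assert cell == pytest.approx(reg.min_q[combo])
                else:
                    assert np.isnan(cell)
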