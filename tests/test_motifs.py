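"""PWM scanning: exact p-values, expression filter, pruning, conservation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from deserthub.core import GenomicInterval
from deserthub.io import BedGraph
from deserthub.motifs import (
    PWM,
    MotifHit,
    annotate_conservation,
    filter_expressed_tfs,
    gc_matched_background,
    log_odds_matrix,
    prune_contained_motifs,
    read_meme,
    scan_sequence,
    score_pvalue_table,
    write_meme,
)
from deserthub.simulate import simulate_sequence_with_motifs

UNIFORM = np.full(4, 0.25)


def _random_pwm(rng, width, motif_id="m", tf="TF"):
    raw = rng.dirichlet(np.full(4, 0.5), size=width).T
    return PWM(motif_id, tf, raw)


def _enumeration_pvalue(pwm, background, granularity, score):
    """Exact tail probability by summing over all 4^W words."""
    q = np.rint(
        log_odds_matrix(pwm, background) / granularity
    ).astype(np.int64)
    total = 0.0
    for word in itertools.product(range(4), repeat=pwm.width):
        s = sum(q[b, k] for k, b in enumerate(word))
        if s >= score:
            total += np.prod([background[b] for b in word])
    return total


class TestPWMValidation:
    def test_column_sums_enforced(self):
        with pytest.raises(ValueError):
            PWM("x", "x", np.full((4, 3), 0.3))
        with pytest.raises(ValueError):
            PWM("x", "x", -np.ones((4, 2)) / 4)

    def test_consensus_and_reverse_complement(self):
        m = np.array([[0.7, 0.1], [0.1, 0.1], [0.1, 0.1], [0.1, 0.7]])
        pwm = PWM("x", "x", m)
        assert pwm.consensus() == "AT"
        assert pwm.reverse_complement().consensus() == "AT"  # palindromic here


class TestExpressionFilter:
    def _pwms(self):
        return [
            PWM("m1", "Tbx5", np.full((4, 2), 0.25)),
            PWM("m2", "Isl1", np.full((4, 2), 0.25)),
            PWM("m3", "Ghost", np.full((4, 2), 0.25)),
        ]

    def test_inclusive_boundary_at_two_fpkm(self):
        expr = pd.DataFrame(
            {"rep1": [2.0, 1.99], "rep2": [2.0, 1.99]}, index=["Tbx5", "Isl1"]
        )
        kept = filter_expressed_tfs(self._pwms(), expr)
        assert [p.tf for p in kept] == ["Tbx5"]

    def test_empty_table_drops_everything(self):
        assert filter_expressed_tfs(self._pwms(), pd.DataFrame()) == []

    def test_absent_tf_dropped(self):
        expr = pd.DataFrame({"rep1": [50.0]}, index=["Tbx5"])
        kept = filter_expressed_tfs(self._pwms(), expr)
        assert [p.tf for p in kept] == ["Tbx5"]

    def test_known_expressed_subset_recovered(self):
        from deserthub.simulate import simulate_expression

        tfs = ["Tbx5", "Gata4", "Isl1", "Tead1"]
        expr = simulate_expression(tfs, expressed={"Tbx5", "Tead1"}, seed=6)
        pwms = [PWM(f"m{i}", tf, np.full((4, 2), 0.25)) for i, tf in enumerate(tfs)]
        assert {p.tf for p in filter_expressed_tfs(pwms, expr)} == {"Tbx5", "Tead1"}


class TestBackground:
    def test_all_at_sequence(self):
        assert np.allclose(
            gc_matched_background("ATATATTA"), [0.5, 0, 0, 0.5]
        )

    def test_half_gc_is_uniform(self):
        assert np.allclose(gc_matched_background("ACGT" * 10), 0.25)

    def test_counting_oracle_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=5_000))
        bg = gc_matched_background(seq)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert bg[1] == pytest.approx(gc / 2) and bg[0] == pytest.approx((1 - gc) / 2)
        assert bg.sum() == pytest.approx(1.0)


class TestExactPValues:
    def test_width1_delta_pwm(self):
        pwm = PWM("d", "d", np.array([[1.0], [0.0], [0.0], [0.0]]))
        table = score_pvalue_table(pwm, UNIFORM)
        assert table.pvalue_of(table.max_score) == pytest.approx(0.25)

    def test_width3_consensus_best_word(self):
        m = np.array(
            [[0.97, 0.01, 0.01], [0.01, 0.97, 0.01],
             [0.01, 0.01, 0.97], [0.01, 0.01, 0.01]]
        )
        table = score_pvalue_table(PWM("c", "c", m), UNIFORM)
        assert table.pvalue_of(table.max_score) == pytest.approx(4.0 ** -3)

    def test_monotone_and_floor(self, rng):
        pwm = _random_pwm(rng, 5)
        table = score_pvalue_table(pwm, UNIFORM)
        assert np.all(np.diff(table.survival) <= 1e-15)
        assert table.pvalue_of(table.offset) == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5, 6])
    def test_dp_matches_enumeration(self, width):
        """DP survival function equals brute-force enumeration over all
        4^W words, at several scores, for non-uniform backgrounds too."""
        rng = np.random.default_rng(100 + width)
        pwm = _random_pwm(rng, width)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        g = 1e-3
        table = score_pvalue_table(pwm, bg, granularity=g)
        probe = np.linspace(table.offset, table.max_score, 7).astype(int)
        for s in probe:
            assert table.pvalue_of(int(s)) == pytest.approx(
                _enumeration_pvalue(pwm, bg, g, int(s)), rel=1e-9, abs=1e-12
            )

    def test_zero_background_without_pseudocount_rejected(self):
        pwm = PWM("x", "x", np.array([[0.5], [0.5], [0.0], [0.0]]))
        with pytest.raises(ValueError):
            score_pvalue_table(pwm, np.array([0.5, 0.0, 0.0, 0.5]), pseudocount=0.0)


class TestScanning:
    def _pwm(self):
        m = np.array(
            [[0.92, 0.02, 0.02, 0.02, 0.92],
             [0.02, 0.02, 0.92, 0.02, 0.02],
             [0.04, 0.94, 0.02, 0.02, 0.04],
             [0.02, 0.02, 0.04, 0.94, 0.02]]
        )
        return PWM("probe", "Tbx5", m)

    def test_planted_instances_recovered_with_strand(self):
        pwm = self._pwm()
        seq, truth = simulate_sequence_with_motifs(
            10_000, gc=0.5, plants=[(pwm, 2_000, "+"), (pwm, 7_000, "-")], seed=3
        )
        hits = scan_sequence(seq, [pwm], p_cutoff=1e-2)
        found = {(h.interval.start, h.strand) for h in hits}
        assert (2_000, "+") in found and (7_000, "-") in found

    def test_strand_symmetry_on_random_sequence(self, rng):
        pwm = self._pwm()
        seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=4_000))
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        flip = {"+": "-", "-": "+"}
        fwd = sorted(
            (h.interval.start, h.strand, round(h.pvalue, 10))
            for h in scan_sequence(seq, [pwm], p_cutoff=1e-2)
        )
        mirrored = sorted(
            (len(seq) - h.interval.end, flip[h.strand], round(h.pvalue, 10))
            for h in scan_sequence(rc, [pwm], p_cutoff=1e-2)
        )
        assert fwd == mirrored

    def test_short_sequence_no_hits_no_error(self):
        assert scan_sequence("ACG", [self._pwm()]) == []

    def test_hit_count_monotone_in_cutoff(self, rng):
        pwm = self._pwm()
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        n_loose = len(scan_sequence(seq, [pwm], p_cutoff=1e-2))
        n_tight = len(scan_sequence(seq, [pwm], p_cutoff=1e-4))
        assert n_tight <= n_loose

    def test_ambiguous_bases_skipped(self):
        pwm = self._pwm()
        seq = "ACGTN" * 200
        hits = scan_sequence(seq, [pwm], p_cutoff=1.0)
        for h in hits:
            assert "N" not in seq[h.interval.start : h.interval.end]


class TestPruning:
    def _hit(self, start, end, tf, p, strand="+"):
        return MotifHit(
            GenomicInterval("s", start, end), strand, f"{tf}_{end-start}",
            tf, 5.0, p,
        )

    def test_nested_same_tf_weaker_inner_dropped(self):
        outer = self._hit(100, 112, "Tbx5", 1e-6)
        inner = self._hit(102, 108, "Tbx5", 1e-5)
        assert prune_contained_motifs([outer, inner]) == [outer]

    def test_nested_different_tf_both_kept(self):
        outer = self._hit(100, 112, "Tbx5", 1e-6)
        inner = self._hit(102, 108, "Gata4", 1e-5)
        assert len(prune_contained_motifs([outer, inner])) == 2

    def test_inner_with_better_pvalue_kept(self):
        outer = self._hit(100, 112, "Tbx5", 1e-4)
        inner = self._hit(102, 108, "Tbx5", 1e-8)
        assert len(prune_contained_motifs([outer, inner])) == 2

    def test_random_nests_match_containment_oracle(self, rng):
        hits = [
            self._hit(int(s), int(s) + int(w), rng.choice(["A", "B"]),
                      float(p))
            for s, w, p in zip(
                rng.integers(0, 500, 30), rng.integers(4, 20, 30),
                rng.uniform(1e-8, 1e-2, 30),
            )
        ]
        got = set(id(h) for h in prune_contained_motifs(hits))
        for h in hits:
            redundant = any(
                o.tf == h.tf
                and o.interval.length() > h.interval.length()
                and o.interval.contains(h.interval)
                and o.pvalue <= h.pvalue
                for o in hits
            )
            assert (id(h) not in got) == redundant


class TestConservation:
    def test_constant_track(self):
        track = BedGraph("s", [0], [1_000], [1.7])
        hit = MotifHit(GenomicInterval("s", 100, 110), "+", "m", "T", 1.0, 0.5)
        [out] = annotate_conservation([hit], track)
        assert out.conservation == pytest.approx(1.7)

    def test_half_covered_hit(self):
        track = BedGraph("s", [105], [115], [2.0])
        hit = MotifHit(GenomicInterval("s", 100, 110), "+", "m", "T", 1.0, 0.5)
        [out] = annotate_conservation([hit], track)
        assert out.conservation == pytest.approx(1.0)

    def test_empty_track_gives_zero(self):
        track = BedGraph("s", [], [], [])
        hit = MotifHit(GenomicInterval("s", 100, 110), "+", "m", "T", 1.0, 0.5)
        [out] = annotate_conservation([hit], track)
        assert out.conservation == 0.0


def test_meme_roundtrip(tmp_path, rng):
    pwms = [_random_pwm(rng, 6, "motif_a", "Tbx5"),
            _random_pwm(rng, 3, "motif_b", "Gata4")]
    path = tmp_path / "t.meme"
    write_meme(path, pwms)
    back = read_meme(path)
    assert [p.motif_id for p in back] == ["motif_a", "motif_b"]
    assert [p.tf for p in back] == ["Tbx5", "Gata4"]
    for a, b in zip(pwms, back):
        assert np.allclose(a.matrix, b.matrix, atol=1e-5)
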