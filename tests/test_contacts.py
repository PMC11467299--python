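"""Contact matrices: binning, masking, balancing, insulation, boundaries."""

import numpy as np
import pytest

from conftest import make_balanced, two_block_matrix

from deserthub.core import GenomicInterval
from deserthub.io import PairTable
from deserthub.contacts import (
    ContactMatrix,
    balance_matrix,
    bin_pairs,
    filter_bins,
    insulation_and_boundaries,
    interdomain_insulation_matrix,
    read_matrix,
    subtract_matrices,
    write_matrix,
)

REGION = GenomicInterval("chr3", 0, 100_000)


class TestBinPairs:
    def test_single_pair_cell(self):
        pairs = PairTable("chr3", [0], [12_000])
        cm = bin_pairs(pairs, REGION, 5_000)
        assert cm.matrix[0, 2] == 1 and cm.matrix[2, 0] == 1
        assert cm.matrix.sum() == 2  # mirrored once

    def test_count_conservation(self, locus_model):
        from deserthub.simulate import simulate_pairs

        pairs = simulate_pairs(locus_model, "heart")
        cm = bin_pairs(pairs, locus_model.region, 5_000)
        iu = np.triu_indices(cm.n_bins)
        assert cm.matrix[iu].sum() == len(pairs)

    def test_empty_input(self):
        cm = bin_pairs(PairTable("chr3", [], []), REGION, 5_000)
        assert cm.matrix.sum() == 0 and cm.n_bins == 20


class TestFilterBins:
    def test_all_zero_bin_masked(self):
        m = np.ones((30, 30))
        m[7, :] = 0
        m[:, 7] = 0
        cm = ContactMatrix(REGION.pad(0, 50_000), 5_000, m, np.ones(30, bool))
        out = filter_bins(cm, min_nnz=5)
        assert not out.mask[7] and out.mask.sum() == 29

    def test_uniform_matrix_keeps_everything(self):
        m = np.full((30, 30), 3.0)
        cm = ContactMatrix(REGION.pad(0, 50_000), 5_000, m, np.ones(30, bool))
        assert filter_bins(cm).mask.all()

    def test_mad_rule_masks_extreme_low_coverage(self):
        """A bin at ~1e-8 of median coverage fails the log10 MAD cut."""
        n = 30
        m = np.full((n, n), 100.0)
        m[3, :] *= 1e-8
        m[:, 3] *= 1e-8
        m[3, 3] = 100e-8
        cm = ContactMatrix(REGION.pad(0, 50_000), 5_000, m, np.ones(n, bool))
        out = filter_bins(cm, min_nnz=1, mad_max=5)
        # direct MAD oracle on log10 marginals
        marg = m.sum(axis=1)
        logm = np.log10(marg)
        med = np.median(logm)
        mad = np.median(np.abs(logm - med))
        expected = logm >= med - 5 * mad
        assert np.array_equal(out.mask, expected)
        assert not out.mask[3]


class TestBalance:
    def test_doubly_stochastic_fixed_point(self):
        n = 20
        m = np.full((n, n), 1.0 / n)
        cm = ContactMatrix(REGION, 5_000, m, np.ones(n, bool))
        bal = balance_matrix(cm, ignore_diags=0)
        b = bal.bias
        assert np.allclose(b, b[0], rtol=1e-6)

    def test_rank_one_balances_to_constant(self):
        """u u^T balances to a constant: the bias absorbs 1/u."""
        rng = np.random.default_rng(2)
        u = rng.uniform(0.5, 4.0, size=25)
        m = np.outer(u, u)
        cm = ContactMatrix(
            GenomicInterval("chr3", 0, 125_000), 5_000, m, np.ones(25, bool)
        )
        bal = balance_matrix(cm, ignore_diags=0, tol=1e-12, max_iters=500)
        vals = bal.matrix[bal.mask][:, bal.mask]
        assert np.allclose(vals, vals[0, 0], rtol=1e-4)
        assert np.allclose(bal.bias * u, (bal.bias * u)[0], rtol=1e-4)

    def test_marginal_equality_and_bias_identity(self, locus_model):
        from deserthub.simulate import simulate_pairs

        pairs = simulate_pairs(locus_model, "limb")
        raw = bin_pairs(pairs, locus_model.region, 5_000)
        masked = filter_bins(raw)
        bal = balance_matrix(masked)
        work = bal.values_with_mask()
        marg = np.nansum(work, axis=1)[bal.mask]
        rel = np.std(marg) / np.mean(marg)
        assert rel < np.sqrt(1e-5) * 2
        # balanced_ij == bias_i * raw_ij * bias_j on retained cells
        idx = np.where(bal.mask)[0][:50]
        sub = bal.matrix[np.ix_(idx, idx)]
        expect = np.outer(bal.bias[idx], bal.bias[idx]) * raw.matrix[np.ix_(idx, idx)]
        assert np.allclose(sub, expect, rtol=1e-6)

    def test_no_retained_bins_rejected(self):
        n = 10
        cm = ContactMatrix(
            GenomicInterval("c", 0, 50_000), 5_000, np.zeros((n, n)),
            np.zeros(n, bool),
        )
        with pytest.raises(ValueError):
            balance_matrix(cm)


class TestSubtractMatrices:
    def test_self_subtraction_zero_and_mask_propagation(self):
        rng = np.random.default_rng(0)
        m = rng.random((20, 20))
        m = m + m.T
        a = make_balanced(m.copy())
        b = make_balanced(m.copy())
        a.mask[3] = False
        b.mask[5] = False
        diff = subtract_matrices(a, b)
        assert np.allclose(diff.matrix, 0)
        assert not diff.mask[3] and not diff.mask[5]
        assert np.isnan(diff.values_with_mask()[3]).all()

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x = rng.random((15, 15))
        y = rng.random((15, 15))
        a = make_balanced(x + x.T)
        b = make_balanced(y + y.T)
        d1 = subtract_matrices(a, b)
        d2 = subtract_matrices(b, a)
        assert np.allclose(d1.matrix, -d2.matrix)

    def test_requires_balanced_same_grid(self):
        a = make_balanced(np.eye(10))
        raw = ContactMatrix(a.region, a.binsize, np.eye(10), np.ones(10, bool))
        with pytest.raises(ValueError):
            subtract_matrices(a, raw)


class TestInsulationBoundaries:
    def test_two_block_junction_found_once(self):
        cm = two_block_matrix(60, 30, 10.0, 2.0, 0.5, seed=0)
        res = insulation_and_boundaries(cm, min_window=50_000)
        strong = [b for b in res.boundaries if b.cls == "strong"]
        near = [b for b in strong if abs(b.bin - 30) <= 1]
        assert len(near) == 1
        # no other strong boundary elsewhere
        assert all(abs(b.bin - 30) <= 1 for b in strong)

    def test_constant_matrix_has_no_boundaries(self):
        cm = make_balanced(np.full((60, 60), 5.0))
        res = insulation_and_boundaries(cm, min_window=50_000)
        assert res.boundaries == []
        interior = res.tad_separation[np.isfinite(res.tad_separation)]
        assert np.allclose(interior, interior[0])

    def test_strong_and_weak_classification(self):
        """A deep junction classifies strong (p<0.01); a marginal one weak
        (0.01 <= p < 0.05)."""
        deep = two_block_matrix(60, 30, 10.0, 2.0, 0.5, seed=0)
        res = insulation_and_boundaries(deep, min_window=50_000)
        b = min(
            (b for b in res.boundaries if abs(b.bin - 30) <= 1),
            key=lambda b: b.pvalue,
        )
        assert b.cls == "strong" and b.pvalue < 0.01
        marginal = two_block_matrix(60, 30, 10.0, 9.75, 1.0, seed=0)
        res = insulation_and_boundaries(marginal, min_window=50_000)
        b = [b for b in res.boundaries if abs(b.bin - 30) <= 1][0]
        assert b.cls == "weak" and 0.01 <= b.pvalue < 0.05

    def test_narrow_matrix_rejected(self):
        cm = make_balanced(np.full((10, 10), 1.0))
        with pytest.raises(ValueError):
            insulation_and_boundaries(cm, min_window=50_000)

    def test_boundary_pvalues_in_unit_interval(self):
        cm = two_block_matrix(60, 30, 10.0, 5.0, 1.0, seed=3)
        res = insulation_and_boundaries(cm, min_window=50_000)
        for b in res.boundaries:
            assert 0.0 <= b.pvalue <= 1.0 and b.pvalue <= b.qvalue <= 1.0


class TestInterdomainMatrix:
    def test_uniform_blocks_are_flat(self):
        cm = make_balanced(np.full((60, 60), 2.0))
        doms = [
            GenomicInterval("chrT", 0, 100_000),
            GenomicInterval("chrT", 100_000, 200_000),
            GenomicInterval("chrT", 200_000, 300_000),
        ]
        z = interdomain_insulation_matrix(cm, doms)
        assert np.allclose(z[np.isfinite(z)], 0.0, atol=1e-9)

    def test_symmetry_on_random_input(self):
        rng = np.random.default_rng(4)
        m = rng.random((60, 60)) + 0.5
        cm = make_balanced(m + m.T)
        doms = [
            GenomicInterval("chrT", 0, 80_000),
            GenomicInterval("chrT", 80_000, 190_000),
            GenomicInterval("chrT", 190_000, 300_000),
        ]
        z = interdomain_insulation_matrix(cm, doms)
        assert np.allclose(z, z.T, equal_nan=True)


class TestMatrixIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        m = rng.integers(0, 10, (20, 20)).astype(float)
        m = m + m.T
        cm = ContactMatrix(REGION, 5_000, m, np.ones(20, bool))
        cm.mask[4] = False
        write_matrix(tmp_path / "bins.tsv", tmp_path / "trip.tsv", cm)
        back = read_matrix(tmp_path / "bins.tsv", tmp_path / "trip.tsv")
        assert np.allclose(back.matrix, cm.matrix)
        assert np.array_equal(back.mask, cm.mask)
        assert back.region == cm.region and back.binsize == cm.binsize
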