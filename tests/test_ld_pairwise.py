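import math
from math import comb

import numpy as np
import pytest

from hapld.errors import FilterError, UndefinedStatisticError
from hapld.ld_pairwise import (
    LDGrid,
    PairwiseLD,
    TwoLocusTable,
    build_grid,
    filter_pairs_by_maf,
    fisher_exact_2x2,
    ld_stats,
    pairwise_ld_scan,
    two_locus_counts,
)

from conftest import make_alignment, random_2x2, table_to_vectors


def T(n11, n12, n21, n22):
    return TwoLocusTable(0, 1, "A", "A", n11, n12, n21, n22)


def fisher_enumeration(n11, n12, n21, n22):
    """Independent oracle: sum hypergeometric probabilities of all tables
    with the observed margins whose probability <= the observed one."""
    n = n11 + n12 + n21 + n22
    row = n11 + n12
    col = n11 + n21
    denom = comb(n, col)

    def prob(x):
        return comb(row, x) * comb(n - row, col - x) / denom

    p_obs = prob(n11)
    lo = max(0, col - (n - row))
    hi = min(row, col)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-12))


class TestTwoLocusCounts:
    def test_perfect_association(self):
        aln = make_alignment(["AA"] * 5 + ["CC"] * 5)
        t = two_locus_counts(aln, 0, 1)
        assert (t.n11, t.n12, t.n21, t.n22) == (5, 0, 0, 5)
        assert (t.allele_a, t.allele_b) == ("A", "A")

    def test_independence_counts(self):
        aln = make_alignment(["AA", "AC", "CA", "CC"] * 3)
        t = two_locus_counts(aln, 0, 1)
        assert (t.n11, t.n12, t.n21, t.n22) == (3, 3, 3, 3)

    def test_relabeling_swaps_columns(self):
        aln = make_alignment(["AA"] * 5 + ["CC"] * 3 + ["AC"] * 2)
        t = two_locus_counts(aln, 0, 1)
        # swap alleles at site 1: A<->C
        swapped = make_alignment(
            [s[0] + {"A": "C", "C": "A"}[s[1]] for s in aln.sequences]
        )
        t2 = two_locus_counts(swapped, 0, 1)
        assert (t2.n11, t2.n12) == (t.n12, t.n11)
        assert (t2.n21, t2.n22) == (t.n22, t.n21)

    def test_non_usable_site_rejected(self):
        aln = make_alignment(["AAG", "ACG", "AC-"])
        with pytest.raises(FilterError):
            two_locus_counts(aln, 0, 1)  # site 0 monomorphic
        with pytest.raises(FilterError):
            two_locus_counts(aln, 1, 2)  # site 2 has a gap


class TestLDStats:
    def test_perfect_ld(self):
        D, dp, r, r2 = ld_stats(T(5, 0, 0, 5))
        assert (D, dp, r, r2) == pytest.approx((0.25, 1.0, 1.0, 1.0))

    def test_independence(self):
        D, dp, r, r2 = ld_stats(T(3, 3, 3, 3))
        assert (D, r2) == pytest.approx((0.0, 0.0))

    def test_intermediate_table(self):
        D, dp, r, r2 = ld_stats(T(4, 1, 1, 4))
        assert D == pytest.approx(0.15)
        assert r2 == pytest.approx(0.36)
        assert dp == pytest.approx(0.6)

    def test_monomorphic_margin_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            ld_stats(T(5, 0, 5, 0))

    def test_r2_equals_squared_correlation(self, rng):
        for _ in range(1000):
            n11, n12, n21, n22 = random_2x2(rng)
            _, _, r, r2 = ld_stats(T(n11, n12, n21, n22))
            x, y = table_to_vectors(n11, n12, n21, n22)
            assert abs(r2 - np.corrcoef(x, y)[0, 1] ** 2) < 1e-12

    def test_allele_relabeling_flips_d_keeps_r2(self, rng):
        for _ in range(200):
            n11, n12, n21, n22 = random_2x2(rng)
            D, _, _, r2 = ld_stats(T(n11, n12, n21, n22))
            D2, _, _, r2b = ld_stats(T(n12, n11, n22, n21))
            assert D2 == pytest.approx(-D, abs=1e-15)
            assert r2b == pytest.approx(r2, abs=1e-12)


class TestFisher:
    def test_mode_table_p_one(self):
        assert fisher_exact_2x2(T(3, 3, 3, 3)) == pytest.approx(1.0)

    def test_extreme_table_16(self):
        assert fisher_exact_2x2(T(8, 0, 0, 8)) == pytest.approx(2 / comb(16, 8))

    def test_extreme_table_10(self):
        assert fisher_exact_2x2(T(5, 0, 0, 5)) == pytest.approx(2 / 252)

    def test_matches_enumeration(self, rng):
        for _ in range(200):
            n11, n12, n21, n22 = random_2x2(rng, n_max=32)
            p = fisher_exact_2x2(T(n11, n12, n21, n22))
            assert p == pytest.approx(fisher_enumeration(n11, n12, n21, n22), rel=1e-9)

    def test_doubling_convention(self):
        t = T(8, 2, 3, 7)
        p_mass = fisher_exact_2x2(t, method="probability")
        p_double = fisher_exact_2x2(t, method="doubling")
        assert 0 < p_mass <= 1 and 0 < p_double <= 1
        assert p_double >= p_mass  # doubling is never smaller here


class TestScan:
    def test_two_sites_perfect_ld(self):
        aln = make_alignment(["AA"] * 4 + ["CC"] * 4)
        pairs, summary = pairwise_ld_scan(aln)
        assert summary.n_pairs == 1
        assert summary.mean_r2 == pytest.approx(1.0)
        assert pairs[0].distance == 1

    def test_monomorphic_dataset_gives_na(self):
        pairs, summary = pairwise_ld_scan(make_alignment(["AAAA"] * 6))
        assert pairs == []
        assert summary.n_pairs == 0
        assert math.isnan(summary.mean_r2)

    def test_pair_count_identity(self):
        for k in (2, 3, 10, 53):
            aln = make_alignment(["A" * k, "A" * k, "C" * k, "C" * k])
            pairs, summary = pairwise_ld_scan(aln, compute_fisher=False)
            assert summary.n_pairs == k * (k - 1) // 2 == len(pairs)

    def test_significance_count_ordering(self):
        from hapld.synthetic_data import SimParams, simulate_haplotypes

        aln = simulate_haplotypes(SimParams(n=20, L=600, theta=0.02, rho=0.01, seed=11))
        _, summary = pairwise_ld_scan(aln)
        assert (
            summary.n_significant_bonferroni
            <= summary.n_significant_nominal
            <= summary.n_pairs
        )

    def test_scan_agrees_with_single_pair_path(self):
        from hapld.synthetic_data import SimParams, simulate_haplotypes

        aln = simulate_haplotypes(SimParams(n=10, L=200, theta=0.02, rho=0.02, seed=2))
        pairs, _ = pairwise_ld_scan(aln)
        for p in pairs[:20]:
            t = two_locus_counts(aln, p.site_i, p.site_j)
            D, dp, r, r2 = ld_stats(t)
            assert p.r2 == pytest.approx(r2, abs=1e-12)
            assert p.fisher_p == pytest.approx(fisher_exact_2x2(t), rel=1e-9)

    def test_maf_filter_keeps_common_pairs_only(self):
        from hapld.alignment_io import extract_sites

        # site 0 singleton (1/6), site 1 and 2 common (3/6)
        seqs = ["CAA", "ACC", "ACC", "AAA", "ACC", "AAA"]
        aln = make_alignment(seqs)
        table = extract_sites(aln)
        pairs, _ = pairwise_ld_scan(aln, site_table=table)
        common = filter_pairs_by_maf(pairs, table, aln.n, min_maf=0.2)
        assert {(p.site_i, p.site_j) for p in common} == {(1, 2)}


class TestGrid:
    def _pairs(self, cols, r2_fn):
        out = []
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                out.append(
                    PairwiseLD(cols[a], cols[b], cols[b] - cols[a], 0, 0, 0,
                               r2_fn(a, b), 1.0, False, False)
                )
        return out

    def test_full_block(self):
        grid = build_grid(self._pairs([5, 10, 20], lambda a, b: 1.0))
        assert grid.blocks == [(0, 2)]
        assert grid.block_spans_bp() == [15]

    def test_no_blocks(self):
        grid = build_grid(self._pairs([5, 10, 20], lambda a, b: 0.0))
        assert grid.blocks == []

    def test_block_broken_by_internal_weak_pair(self):
        # adjacent pairs strong but the (0,2) pair weak: no 3-site block
        grid = build_grid(
            self._pairs([0, 1, 2], lambda a, b: 0.9 if b - a == 1 else 0.1)
        )
        assert grid.blocks == [(0, 1)]

    def test_matrix_symmetric_unit_diagonal(self):
        from hapld.synthetic_data import SimParams, simulate_haplotypes

        aln = simulate_haplotypes(SimParams(n=12, L=300, theta=0.02, rho=0.01, seed=9))
        pairs, _ = pairwise_ld_scan(aln, compute_fisher=False)
        grid = build_grid(pairs)
        assert np.allclose(grid.matrix, grid.matrix.T, equal_nan=True)
        assert np.allclose(np.diag(grid.matrix), 1.0)
        assert isinstance(grid, LDGrid)
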