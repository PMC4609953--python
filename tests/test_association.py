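"""Association scan calibration, Bonferroni/RMIP semantics, Lewontin D'
(hand-computed tables and invariants), LD blocks and the enrichment
tests against an exhaustive hypergeometric oracle."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from skimqtl import association
from skimqtl.association import AssocParams
from skimqtl.core import A, B, MISSING, GenotypeMatrix


def random_matrix(n_lines, n_sites, seed=0, missing=0.0):
    rng = np.random.default_rng(seed)
    calls = rng.integers(0, 2, size=(n_lines, n_sites)).astype(np.int8)
    if missing:
        calls[rng.random(calls.shape) < missing] = MISSING
    sites = pd.DataFrame({"chrom": "Ca1", "pos": np.arange(1, n_sites + 1) * 1000})
    return GenotypeMatrix(
        sites=sites, lines=[f"L{i}" for i in range(n_lines)], calls=calls
    )


class TestSingleMarkerAssociation:
    def test_planted_qtl_beats_bonferroni(self, skim, phenotypes):
        y = phenotypes.table["planted__env1"].to_numpy()
        assoc = association.single_marker_association(skim, y)
        cutoff = 0.05 / skim.n_sites
        site = phenotypes.qtl_sites.iloc[0]
        near = assoc[
            (assoc["chrom"] == site["chrom"])
            & ((assoc["pos"] - site["site_pos"]).abs() < 500_000)
        ]
        assert near["p"].min() < cutoff

    def test_null_pvalues_uniform(self):
        matrix = random_matrix(200, 5000, seed=1)
        rng = np.random.default_rng(2)
        y = rng.normal(size=200)
        assoc = association.single_marker_association(matrix, y)
        ks = stats.kstest(assoc["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_equal_class_means_not_significant(self):
        calls = np.array([[A] * 1 + [B] * 1] * 200, dtype=np.int8).reshape(200, 2)
        calls[:100, 0] = A
        calls[100:, 0] = B
        matrix = random_matrix(200, 2, seed=3)
        y = np.r_[np.zeros(100), np.zeros(100)] + np.tile([0.0, 1.0], 100)
        assoc = association.single_marker_association(matrix, y)
        assert (assoc["p"] > 0.001).all()

    def test_monomorphic_flagged(self):
        matrix = random_matrix(50, 2, seed=4)
        calls = matrix.calls.copy()
        calls[:, 0] = A
        matrix = GenotypeMatrix(sites=matrix.sites, lines=matrix.lines, calls=calls)
        assoc = association.single_marker_association(matrix, np.random.default_rng(5).normal(size=50))
        assert bool(assoc.loc[0, "monomorphic"])
        assert assoc.loc[0, "p"] == 1.0


class TestBonferroni:
    def test_cutoff_arithmetic(self):
        # 18,935 tests at alpha 0.05 -> per-test cutoff ~2.64e-6
        m = 18_935
        pvals = np.full(m, 1.0)
        pvals[0] = 2.6e-6
        mask = association.bonferroni_mtas(pvals, alpha=0.05)
        assert 0.05 / m == pytest.approx(2.64e-6, abs=0.005e-6)
        assert mask[0] and mask.sum() == 1

    def test_boundary_included(self):
        pvals = np.array([0.05 / 10] * 10)
        assert association.bonferroni_mtas(pvals, alpha=0.05).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            association.bonferroni_mtas(np.array([]))


class TestRmip:
    def test_deterministic(self, skim, phenotypes):
        y = phenotypes.table["planted__env1"].to_numpy()
        params = AssocParams(n_resamples=20, seed=6)
        c1 = association.rmip(skim, y, params)
        c2 = association.rmip(skim, y, params)
        np.testing.assert_array_equal(c1, c2)

    def test_planted_qtl_high_rmip_null_low(self, skim, phenotypes):
        y = phenotypes.table["planted__env1"].to_numpy()
        params = AssocParams(n_resamples=50, seed=7)
        counts = association.rmip(skim, y, params)
        site = phenotypes.qtl_sites.iloc[0]
        near = (
            (skim.sites["chrom"] == site["chrom"])
            & ((skim.sites["pos"] - site["site_pos"]).abs() < 300_000)
        ).to_numpy()
        assert counts[near].max() >= 45  # stable signal
        far = (skim.sites["chrom"] == "Ca2").to_numpy()
        assert (counts[far] >= params.rmip_min).mean() <= 0.01

    def test_null_retention_below_one_percent(self):
        matrix = random_matrix(150, 800, seed=8)
        y = np.random.default_rng(9).normal(size=150)
        counts = association.rmip(matrix, y, AssocParams(n_resamples=30, seed=10))
        assert (counts >= 5).mean() <= 0.01


class TestLewontinDprime:
    def from_counts(self, ab, a_b, b_a, bb):
        """two-locus haplotype counts: (A,A), (A,B), (B,A), (B,B)."""
        gi = np.array([A] * (ab + a_b) + [B] * (b_a + bb), dtype=np.int8)
        gj = np.array([A] * ab + [B] * a_b + [A] * b_a + [B] * bb, dtype=np.int8)
        return gi, gj

    def test_complete_ld(self):
        gi, gj = self.from_counts(5, 0, 0, 5)
        est = association.lewontin_dprime(gi, gj, min_scorable=10)
        assert est.D == pytest.approx(0.25)
        assert est.Dprime == pytest.approx(1.0)

    def test_hand_computed_intermediate(self):
        gi, gj = self.from_counts(4, 1, 1, 4)
        est = association.lewontin_dprime(gi, gj, min_scorable=10)
        assert est.D == pytest.approx(0.15)
        assert est.Dmax == pytest.approx(0.25)
        assert est.Dprime == pytest.approx(0.6)

    def test_independence_zero(self):
        gi, gj = self.from_counts(4, 4, 4, 4)
        est = association.lewontin_dprime(gi, gj, min_scorable=16)
        assert est.Dprime == pytest.approx(0.0)

    def test_monomorphic_rejected(self):
        gi = np.array([A] * 30, dtype=np.int8)
        with pytest.raises(ValueError, match="monomorphic"):
            association.lewontin_dprime(gi, gi, min_scorable=20)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        st.tuples(
            st.integers(1, 30), st.integers(0, 30), st.integers(0, 30), st.integers(1, 30)
        )
    )
    def test_bounded_and_label_swap_antisymmetric(self, counts):
        ab, a_b, b_a, bb = counts
        if ab + a_b == 0 or b_a + bb == 0:
            return
        gi, gj = self.from_counts(ab, a_b, b_a, bb)
        if len(set(gj.tolist())) < 2:
            return
        est = association.lewontin_dprime(gi, gj, min_scorable=2)
        assert abs(est.Dprime) <= 1.0 + 1e-12
        swapped = association.lewontin_dprime(gi, (1 - gj).astype(np.int8), min_scorable=2)
        assert swapped.Dprime == pytest.approx(-est.Dprime, abs=1e-9)


class TestLdBlocks:
    def test_internal_run_block(self):
        pos = np.array([100, 200, 300, 400, 500]) * 1000
        ld = pd.DataFrame(
            {"pos_i": pos[:-1], "pos_j": pos[1:],
             "Dprime": 1.0, "significant": [False, True, True, False]}
        )
        start, end, members = association.ld_block_for_gene(
            gene_start=280_000, gene_end=320_000, snp_positions=pos, ld_pairs=ld
        )
        assert members.tolist() == [1, 2, 3]
        assert (start, end) == (200_000, 400_000)

    def test_snp_desert_fallback(self):
        pos = np.array([100, 110, 120]) * 1000
        ld = pd.DataFrame(
            {"pos_i": pos[:-1], "pos_j": pos[1:], "Dprime": 1.0,
             "significant": [True, True]}
        )
        start, end, members = association.ld_block_for_gene(
            gene_start=5_000_000, gene_end=5_010_000, snp_positions=pos,
            ld_pairs=ld, fallback_pad=80_000,
        )
        assert (start, end) == (4_920_000, 5_090_000)
        assert members.size == 0

    def test_no_snps_requires_pad(self):
        with pytest.raises(ValueError):
            association.ld_block_for_gene(100, 200, np.array([]), pd.DataFrame())

    def test_median_complete_ld_distance(self):
        # three SNPs in complete LD at 10 kb spacing
        calls = np.tile(np.array([[A], [A], [B], [B]], dtype=np.int8), (5, 3))
        sites = pd.DataFrame({"chrom": "Ca1", "pos": [10_000, 20_000, 30_000]})
        matrix = GenotypeMatrix(
            sites=sites, lines=[f"L{i}" for i in range(20)], calls=calls
        )
        m = association.median_complete_ld_distance(matrix, "Ca1", min_scorable=10)
        assert m == 10_000.0


class TestEnrichment:
    def test_hypergeometric_matches_exhaustive_enumeration(self):
        # brute force over all C(N, K) significant-set placements, N <= 12
        for n_pop, n_sig, n_block, k in [(10, 4, 3, 3), (12, 5, 4, 2), (9, 3, 5, 1)]:
            block = set(range(n_block))
            hits = 0
            total = 0
            for sig in itertools.combinations(range(n_pop), n_sig):
                total += 1
                if len(block & set(sig)) >= k:
                    hits += 1
            assert association.hypergeometric_tail(
                n_pop, n_sig, n_block, k
            ) == pytest.approx(hits / total)

    def test_worked_example(self):
        assert association.hypergeometric_tail(10, 4, 3, 3) == pytest.approx(
            4 / math.comb(10, 3)
        )

    def test_zero_hits_not_enriched(self):
        pos = np.arange(1, 21) * 1000
        rmip_counts = np.zeros(20, dtype=int)
        rmip_counts[15:] = 10  # significant SNPs all outside the block
        blocks = pd.DataFrame(
            [{"gene_id": "g", "block_start": 1, "block_end": 5_000}]
        )
        out = association.enrichment_test(
            blocks, pos, rmip_counts, AssocParams(n_enrich_permutations=200, seed=1)
        )
        row = out.iloc[0]
        assert row["colocalization_weight"] == 0.0
        assert row["hypergeometric_p"] == 1.0
        assert not row["enriched"]

    def test_saturated_block_permutation_p_one(self):
        pos = np.arange(1, 11) * 1000
        rmip_counts = np.zeros(10, dtype=int)
        rmip_counts[:3] = 8
        blocks = pd.DataFrame(
            [{"gene_id": "g", "block_start": 1, "block_end": 20_000}]
        )
        out = association.enrichment_test(
            blocks, pos, rmip_counts, AssocParams(n_enrich_permutations=100, seed=2)
        )
        assert out.iloc[0]["permutation_p"] == 1.0

    def test_permutation_agrees_with_hypergeometric_for_equal_weights(self):
        # equal RMIP weights make the permutation weight a pure count, so
        # its tail probability is the hypergeometric one
        rng = np.random.default_rng(3)
        n_pop, n_sig = 40, 8
        pos = np.arange(1, n_pop + 1) * 1000
        rmip_counts = np.zeros(n_pop, dtype=int)
        rmip_counts[rng.choice(n_pop, n_sig, replace=False)] = 10
        blocks = pd.DataFrame(
            [{"gene_id": "g", "block_start": 1, "block_end": 12_500}]
        )
        n_perm = 10_000
        out = association.enrichment_test(
            blocks, pos, rmip_counts, AssocParams(n_enrich_permutations=n_perm, seed=4)
        )
        row = out.iloc[0]
        k = int(row["n_block_significant"])
        expected = association.hypergeometric_tail(n_pop, n_sig, int(row["n_block_snps"]), k)
        se = np.sqrt(expected * (1 - expected) / n_perm)
        assert abs(row["permutation_p"] - expected) <= 3 * se + 1e-6

    def test_planted_gene_recovered(self, skim, phenotypes):
        # the gene sitting on the planted QTL is enriched; random far
        # genes are not
        y = phenotypes.table["planted__env1"].to_numpy()
        params = AssocParams(n_resamples=50, n_enrich_permutations=2000, seed=5)
        counts = association.rmip(skim, y, params)
        on_ca1 = skim.site_mask("Ca1")
        pos = skim.sites["pos"].to_numpy()[on_ca1]
        site = phenotypes.qtl_sites.iloc[0]
        blocks = pd.DataFrame(
            [
                {"gene_id": "planted", "block_start": site["site_pos"] - 400_000,
                 "block_end": site["site_pos"] + 400_000},
                {"gene_id": "far", "block_start": 2_000_000, "block_end": 2_800_000},
            ]
        )
        out = association.enrichment_test(blocks, pos, counts[on_ca1], params)
        assert bool(out.set_index("gene_id").loc["planted", "enriched"])
        assert not bool(out.set_index("gene_id").loc["far", "enriched"])
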