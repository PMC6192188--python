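import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapgeo import (
    AnalysisError,
    HaplotypeTable,
    gene_diversity,
    nst_gst_test,
    nucleotide_diversity,
    permut_statistics,
)
from conftest import random_distance_matrix, random_haplotype_table
from _oracles import brute_force_pi


class TestGeneDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((3, 16, 1), 0.353),            # the most diverse chloroplast population
            ((18, 1), 0.105),
            ((3, 13), 0.325),
            ((7, 2, 11), 0.595),
            ((161, 32, 38, 16, 3, 3), 0.554),  # pooled species-level counts
            ((20,), 0.0),
        ],
    )
    def test_published_values(self, counts, expected):
        h, _ = gene_diversity(counts)
        assert round(h, 3) == expected

    def test_sd_matches_published_value(self):
        _, sd = gene_diversity((18, 1))
        assert round(sd, 3) == 0.092

    def test_monomorphic_is_zero_with_zero_sd(self):
        h, sd = gene_diversity((15,))
        assert h == 0.0 and sd == 0.0

    def test_too_small_sample_rejected(self):
        with pytest.raises(AnalysisError):
            gene_diversity((1,))

    @given(st.lists(st.integers(0, 30), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_range_and_monomorphy_iff_zero(self, counts):
        if sum(counts) < 2:
            return
        h, sd = gene_diversity(counts)
        assert 0.0 <= h < 1.0
        assert sd >= 0.0
        polymorphic = sum(c > 0 for c in counts) > 1
        assert (h > 0) == polymorphic


class TestNucleotideDiversity:
    def test_two_sequences_closed_form(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        pi, _ = nucleotide_diversity((1, 1), d, 100)
        assert pi == pytest.approx(0.01)

    def test_monomorphic_is_zero(self):
        pi, sd = nucleotide_diversity((9,), np.zeros((1, 1)), 500)
        assert pi == 0.0 and sd == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_pair_mean(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        d = random_distance_matrix(rng, k)
        counts = rng.integers(1, 6, size=k)
        L = 50
        pi, _ = nucleotide_diversity(counts, d, L)
        haps = np.repeat(np.arange(k), counts)
        assert pi == pytest.approx(brute_force_pi(haps, d, L))

    def test_pi_zero_whenever_h_zero(self, cp_collapsed):
        _, table = cp_collapsed
        d = np.ones((6, 6)) - np.eye(6)
        for p in table.populations:
            c = table.counts.loc[p].to_numpy()
            h, _ = gene_diversity(c)
            pi, _ = nucleotide_diversity(c, d, 100)
            if h == 0:
                assert pi == 0.0


class TestPermutStatistics:
    def test_cp_within_population_diversity(self, cp_collapsed):
        _, table = cp_collapsed
        res = permut_statistics(table)
        assert round(res.hs, 3) == 0.049

    def test_its_within_population_diversity(self, its_collapsed):
        _, table = its_collapsed
        res = permut_statistics(table)
        assert round(res.hs, 3) == 0.142

    def test_two_fixed_populations_give_full_differentiation(self):
        table = HaplotypeTable(pd.DataFrame(
            [[10, 0], [0, 10]], index=["P1", "P2"], columns=["H1", "H2"]))
        res = permut_statistics(table)
        assert res.hs == 0.0
        assert res.gst == pytest.approx(1.0)

    def test_identical_frequency_vectors_give_no_differentiation(self):
        # unbiased HS slightly exceeds the plugin total diversity at finite n,
        # so GST vanishes (from below) as samples grow
        table = HaplotypeTable(pd.DataFrame(
            [[500, 500], [500, 500], [500, 500]], index=list("ABC"),
            columns=["H1", "H2"]))
        res = permut_statistics(table)
        assert res.gst == pytest.approx(0.0, abs=0.005)
        assert res.gst <= 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_gst_identity_and_nst_equals_gst_when_equidistant(self, seed):
        rng = np.random.default_rng(seed)
        table = HaplotypeTable(random_haplotype_table(rng))
        k = len(table.haplotype_ids)
        res = permut_statistics(table, dist=3.0 * (1 - np.eye(k)))
        assert res.gst == pytest.approx(1 - res.hs / res.ht, abs=1e-12)
        assert res.nst == pytest.approx(res.gst, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_label_invariance(self, seed):
        rng = np.random.default_rng(seed)
        df = random_haplotype_table(rng, n_haps=4)
        d = random_distance_matrix(rng, 4)
        perm = rng.permutation(4)
        df2 = df.iloc[:, perm]
        res1 = permut_statistics(HaplotypeTable(df), d)
        res2 = permut_statistics(HaplotypeTable(df2), d[np.ix_(perm, perm)])
        assert res1.hs == pytest.approx(res2.hs, abs=1e-12)
        assert res1.ht == pytest.approx(res2.ht, abs=1e-12)
        assert res1.nst == pytest.approx(res2.nst, abs=1e-12)

    def test_single_population_rejected(self):
        table = HaplotypeTable(pd.DataFrame([[5, 5]], index=["P1"], columns=["H1", "H2"]))
        with pytest.raises(AnalysisError):
            permut_statistics(table)


class TestNstGstTest:
    def test_equidistant_haplotypes_never_significant(self, rng):
        table = HaplotypeTable(random_haplotype_table(rng, n_pops=4, n_haps=3))
        d = 2.0 * (1 - np.eye(3))
        res = nst_gst_test(table, d, n_perm=99, seed=0)
        assert res.p_value >= 0.5

    def test_fixture_shows_no_phylogeographic_structure(self, cp_collapsed):
        col, table = cp_collapsed
        res = nst_gst_test(table, col.distances, n_perm=199, seed=11)
        assert res.p_value > 0.05

    def test_strong_structure_is_detected(self):
        # two distance-clustered groups of five haplotypes each, segregated
        # by region; enough haplotypes that relabelling can break the
        # cluster structure (few-haplotype matrices have large automorphism
        # groups, which bounds the attainable p from below)
        rng = np.random.default_rng(3)
        within = random_distance_matrix(rng, 5, max_d=3)
        d = np.full((10, 10), 9.0)
        d[:5, :5] = within
        d[5:, 5:] = random_distance_matrix(rng, 5, max_d=3)
        np.fill_diagonal(d, 0.0)
        profiles = []
        for p in range(3):
            row = np.zeros(10, dtype=int)
            row[:5] = rng.multinomial(12, rng.dirichlet(np.ones(5)))
            profiles.append(row)
        for p in range(3):
            row = np.zeros(10, dtype=int)
            row[5:] = rng.multinomial(12, rng.dirichlet(np.ones(5)))
            profiles.append(row)
        counts = pd.DataFrame(profiles, index=[f"P{i}" for i in range(6)],
                              columns=[f"H{j}" for j in range(10)])
        counts = counts.loc[:, counts.sum(axis=0) > 0]
        keep = [int(c[1:]) for c in counts.columns]
        res = nst_gst_test(HaplotypeTable(counts), d[np.ix_(keep, keep)],
                           n_perm=999, seed=5)
        assert res.nst > res.gst
        assert res.p_value < 0.05

    def test_reproducible_with_seed(self, cp_collapsed):
        col, table = cp_collapsed
        a = nst_gst_test(table, col.distances, n_perm=99, seed=42)
        b = nst_gst_test(table, col.distances, n_perm=99, seed=42)
        assert a.p_value == b.p_value


class TestPooling:
    def test_species_h_from_pooled_counts_equals_concatenated_sample(self, cp_collapsed):
        col, table = cp_collapsed
        pooled_h, _ = gene_diversity(table.total_counts)
        concat_h, _ = gene_diversity(col.counts)
        assert pooled_h == pytest.approx(concat_h, abs=1e-15)
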