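import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapgeo import Alignment, AnalysisError, collapse_haplotypes, tabulate_by_population

from _oracles import brute_force_partition


def random_alignment(rng, n=5, L=20, alphabet="AC"):
    seqs = ["".join(rng.choice(list(alphabet), size=L)) for _ in range(n)]
    return Alignment([f"s{i}" for i in range(n)], seqs)


class TestCollapse:
    def test_cp_fixture_counts(self, cp_collapsed):
        col, _ = cp_collapsed
        assert len(col.haplotype_ids) == 6
        assert col.distances.n_segregating == 7

    def test_its_fixture_counts(self, its_collapsed):
        col, _ = its_collapsed
        assert len(col.haplotype_ids) == 6
        assert col.distances.n_segregating == 4
        # the two indel columns are excluded before ribotype definition
        assert len(col.retained_columns) == 606 - 2

    def test_identical_sequences_single_haplotype(self):
        aln = Alignment(["a", "b", "c"], ["ACGT"] * 3)
        col = collapse_haplotypes(aln)
        assert col.haplotype_ids == ["H1"]
        assert col.distances.n_segregating == 0
        assert col.distances.matrix.shape == (1, 1)

    def test_all_columns_gapped_is_an_error(self):
        aln = Alignment(["a", "b"], ["A-", "G-"])
        # second column gapped everywhere; first column fine -> works
        assert collapse_haplotypes(aln).retained_columns == [0]
        aln2 = Alignment(["a", "b"], ["--", "--"])
        with pytest.raises(AnalysisError):
            collapse_haplotypes(aln2)

    @pytest.mark.parametrize("trial", range(10))
    def test_partition_matches_brute_force(self, rng, trial):
        aln = random_alignment(np.random.default_rng(trial), n=6, L=12)
        col = collapse_haplotypes(aln)
        mine = {}
        for i, rid in enumerate(aln.ids):
            mine.setdefault(col.assignment[rid], []).append(i)
        assert {frozenset(g) for g in mine.values()} == set(brute_force_partition(aln.seqs))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_record_order_never_changes_partition_or_distances(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=6, L=10)
        perm = rng.permutation(aln.n)
        shuffled = Alignment([aln.ids[i] for i in perm], [aln.seqs[i] for i in perm])
        a, b = collapse_haplotypes(aln), collapse_haplotypes(shuffled)
        part_a = {frozenset(v.index) for _, v in a.assignment.groupby(a.assignment)}
        part_b = {frozenset(v.index) for _, v in b.assignment.groupby(b.assignment)}
        assert part_a == part_b
        tri = np.triu_indices(len(a.haplotype_ids), k=1)
        assert sorted(a.distances.matrix[tri]) == sorted(b.distances.matrix[tri])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_hamming_distances_form_a_metric(self, seed):
        aln = random_alignment(np.random.default_rng(seed), n=8, L=15, alphabet="ACGT")
        d = collapse_haplotypes(aln).distances.matrix
        k = d.shape[0]
        assert np.allclose(d, d.T)
        for i in range(k):
            for j in range(k):
                for m in range(k):
                    assert d[i, j] <= d[i, m] + d[m, j] + 1e-12

    def test_distances_bounded_by_segregating_sites(self, cp_collapsed):
        col, _ = cp_collapsed
        assert col.distances.matrix.max() <= col.distances.n_segregating

    def test_pairwise_complete_keeps_all_columns(self):
        aln = Alignment(["a", "b", "c"], ["AC-T", "ACGT", "GCGT"])
        col = collapse_haplotypes(aln, gap_policy="pairwise_complete")
        assert col.retained_columns == [0, 1, 2, 3]
        assert len(col.haplotype_ids) == 3
        d = col.distances
        # a vs b: column 2 skipped (gap), others equal -> 0
        assert d.matrix[0, 1] == 0
        assert d.matrix[1, 2] == 1


class TestTabulate:
    def test_ml_population_counts(self, cp_collapsed, cp_label_map):
        _, table = cp_collapsed
        ml = table.counts.loc["ML"]
        assert ml[cp_label_map["H5"]] == 3
        assert ml[cp_label_map["H4"]] == 16
        assert ml[cp_label_map["H2"]] == 1
        assert table.sample_sizes["ML"] == 20

    def test_thirteen_fixed_populations(self, cp_collapsed):
        _, table = cp_collapsed
        assert len(table.monomorphic_populations()) == 13

    def test_count_conservation(self, cp_collapsed, cp_fixture):
        _, table = cp_collapsed
        assert table.n_total == cp_fixture.alignment.n
        assert (table.sample_sizes == table.counts.sum(axis=1)).all()

    def test_single_population(self):
        from hapgeo.io import PopulationMap

        aln = Alignment(["a", "b", "c"], ["ACGT", "ACGT", "GCGT"])
        col = collapse_haplotypes(aln)
        pm = PopulationMap({"a": "P1", "b": "P1", "c": "P1"})
        table = tabulate_by_population(col, pm)
        assert list(table.counts.index) == ["P1"]
        assert table.counts.loc["P1"].sum() == 3
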