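import math

import numpy as np
import pytest

from hapgeo import (
    AnalysisError,
    InputError,
    bootstrap_gof,
    expansion_time,
    fit_sudden_expansion,
    fus_fs,
    mismatch_from_counts,
    mismatch_histogram,
    net_divergence_per_site,
    raggedness,
    strict_clock_divergence,
    sudden_expansion_pmf,
    tajimas_d,
)
from hapgeo.demography import ewens_log_pmf

from _oracles import fus_fs_exact, raggedness_oracle, tajima_d_textbook


class TestMismatchHistogram:
    def test_identical_sample_all_mass_at_zero(self):
        d = np.zeros((1, 1))
        hist = mismatch_from_counts([12], d)
        assert hist.tolist() == [1.0]

    def test_two_haplotype_pair_counting(self):
        # 50/50 split of n=100 at distance 3: exact combinatorial masses
        d = np.array([[0.0, 3.0], [3.0, 0.0]])
        hist = mismatch_from_counts([50, 50], d)
        pairs0 = 2 * math.comb(50, 2)
        assert hist[0] == pytest.approx(pairs0 / math.comb(100, 2))
        assert hist[3] == pytest.approx(2500 / math.comb(100, 2))
        assert hist[1] == hist[2] == 0.0

    def test_individual_and_count_paths_agree(self, cp_collapsed):
        col, table = cp_collapsed
        a = mismatch_histogram(col.indices(), col.distances)
        b = mismatch_from_counts(table.total_counts, col.distances)
        np.testing.assert_allclose(a, b)

    def test_fixture_histogram_is_unimodal_after_zero_class(self, cp_collapsed):
        col, table = cp_collapsed
        hist = mismatch_from_counts(table.total_counts, col.distances)
        assert hist.sum() == pytest.approx(1.0)
        interior = hist[1:]
        peak = int(np.argmax(interior))
        assert all(np.diff(interior[peak:]) <= 1e-12)  # single interior mode


class TestSuddenExpansionModel:
    def test_probabilities_sum_to_one(self):
        for tau, th0, th1 in [(0.0, 1.0, 1.0), (3.0, 1.0, 100.0), (12.0, 0.2, 1e4)]:
            pmf = sudden_expansion_pmf(400, tau, th0, th1)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-6)
            assert (pmf >= -1e-12).all()

    def test_tau_zero_is_ancestral_equilibrium(self):
        pmf = sudden_expansion_pmf(50, 0.0, 2.0, 100.0)
        j = np.arange(50)
        eq = 2.0**j / 3.0 ** (j + 1)
        np.testing.assert_allclose(pmf, eq, atol=1e-12)

    def test_self_consistency_recovery(self):
        truth = (3.0, 1.0, 100.0)
        hist = sudden_expansion_pmf(25, *truth)
        fit = fit_sudden_expansion(hist)
        assert fit.ssd <= 1e-10
        assert fit.tau == pytest.approx(truth[0], abs=1e-3)
        assert fit.theta0 == pytest.approx(truth[1], abs=1e-3)

    def test_degenerate_single_class_returns_zero_tau(self):
        fit = fit_sudden_expansion([1.0])
        assert fit.tau == 0.0
        assert "degenerate" in fit.flags[0]

    def test_all_zero_difference_data(self):
        fit = fit_sudden_expansion([1.0, 0.0, 0.0])
        assert fit.tau == pytest.approx(0.0, abs=1e-6)


class TestRaggedness:
    def test_hand_computed_two_class_case(self):
        # (0.5-0)^2 + (0.5-0.5)^2 + (0-0.5)^2 under the padded convention
        assert raggedness([0.5, 0.5]) == pytest.approx(0.5)

    def test_smooth_less_ragged_than_permuted(self):
        smooth = 0.5 ** np.arange(1, 8)
        rough = smooth[[3, 0, 5, 2, 6, 1, 4]]
        assert raggedness(smooth) < raggedness(rough)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_loop(self, seed):
        rng = np.random.default_rng(seed)
        hist = rng.dirichlet(np.ones(rng.integers(2, 12)))
        assert raggedness(hist) == pytest.approx(raggedness_oracle(hist), abs=1e-14)


class TestBootstrapGof:
    def test_zero_replicates_rejected(self, cp_collapsed):
        col, table = cp_collapsed
        hist = mismatch_from_counts(table.total_counts, col.distances)
        fit = fit_sudden_expansion(hist)
        with pytest.raises(InputError):
            bootstrap_gof(hist, fit, 253, n_boot=0)

    def test_seeded_reproducibility_and_p_range(self):
        hist = sudden_expansion_pmf(12, 4.0, 0.5, 50.0)
        fit = fit_sudden_expansion(hist)
        a = bootstrap_gof(hist, fit, 40, n_boot=30, seed=6)
        b = bootstrap_gof(hist, fit, 40, n_boot=30, seed=6)
        assert (a.p_ssd, a.p_raggedness) == (b.p_ssd, b.p_raggedness)
        assert 1 / 31 <= a.p_ssd <= 1.0

    def test_model_generated_data_not_rejected(self):
        # data drawn from the fitted model itself should rarely reject
        from hapgeo.simulate import simulate_mismatch_counts

        rng = np.random.default_rng(12)
        diffs = simulate_mismatch_counts(60, 5.0, 0.5, 80.0, rng)
        hist = np.bincount(diffs) / len(diffs)
        fit = fit_sudden_expansion(hist)
        res = bootstrap_gof(hist, fit, 60, n_boot=60, seed=3)
        assert res.p_ssd > 0.05


class TestTajimasD:
    def test_zero_when_khat_equals_watterson(self):
        n, S = 30, 12
        a1 = sum(1.0 / i for i in range(1, n))
        d, _ = tajimas_d(n, S, S / a1)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_negative_for_published_inputs(self):
        # n=253, S=7, mean pairwise differences = pi * L = 0.00063 * 1531
        d, _ = tajimas_d(253, 7, 0.00063 * 1531)
        assert d < 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_textbook_coefficients(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        S = int(rng.integers(1, 40))
        khat = float(rng.uniform(0, 10))
        d, _ = tajimas_d(n, S, khat)
        assert d == pytest.approx(tajima_d_textbook(n, S, khat), abs=1e-12)

    def test_s_zero_rejected(self):
        with pytest.raises(AnalysisError):
            tajimas_d(20, 0, 0.0)

    def test_p_value_in_unit_interval(self):
        for khat in (0.5, 2.0, 5.0):
            _, p = tajimas_d(50, 10, khat)
            assert 0.0 <= p <= 1.0


class TestFusFs:
    def test_ewens_distribution_normalised(self):
        logpmf = ewens_log_pmf(10, 2.0)
        assert np.exp(logpmf).sum() == pytest.approx(1.0, abs=1e-12)

    def test_exact_rational_oracle_small_case(self):
        assert fus_fs(5, 2, 1.0) == pytest.approx(fus_fs_exact(5, 2, 1), abs=1e-10)
        # hand value: S' = 1 - 24/120 = 4/5, Fs = ln(4)
        assert fus_fs(5, 2, 1.0) == pytest.approx(math.log(4.0), abs=1e-10)

    @pytest.mark.parametrize("n,k0,theta", [(8, 3, 2), (12, 5, 1), (6, 6, 3)])
    def test_matches_exact_rational_oracle(self, n, k0, theta):
        assert fus_fs(n, k0, theta) == pytest.approx(
            fus_fs_exact(n, k0, theta), abs=1e-9)

    def test_theta_to_zero_limit(self):
        with pytest.warns(UserWarning):
            assert fus_fs(10, 3, 0.0) == -math.inf

    def test_large_sample_finite(self):
        fs = fus_fs(253, 6, 1.18)
        assert math.isfinite(fs)


class TestExpansionTime:
    def test_closed_form_published_inputs(self):
        est = expansion_time(1.488, 2e-9, 1531, 10)
        assert est.t_years == pytest.approx(2.43e5, rel=0.01)
        assert est.t_generations == pytest.approx(est.t_years / 10)

    def test_zero_tau_zero_time(self):
        est = expansion_time(0.0, 2e-9, 1531, 10)
        assert est.t_years == 0.0

    def test_scaling_laws(self):
        base = expansion_time(1.5, 2e-9, 1000, 10)
        assert expansion_time(3.0, 2e-9, 1000, 10).t_years == pytest.approx(2 * base.t_years)
        assert expansion_time(1.5, 4e-9, 1000, 10).t_years == pytest.approx(base.t_years / 2)
        assert expansion_time(1.5, 2e-9, 2000, 10).t_years == pytest.approx(base.t_years / 2)

    def test_bad_inputs_rejected(self):
        with pytest.raises(InputError):
            expansion_time(1.0, 0.0, 1531, 10)
        with pytest.raises(InputError):
            expansion_time(-1.0, 2e-9, 1531, 10)


class TestStrictClock:
    def test_closed_form(self):
        assert strict_clock_divergence(0.004, 2e-9) == pytest.approx(1.0e6)
        assert strict_clock_divergence(0.0, 2e-9) == 0.0

    def test_linearity(self):
        t1 = strict_clock_divergence(0.001, 1e-9)
        t2 = strict_clock_divergence(0.002, 1e-9)
        assert t2 == pytest.approx(2 * t1)

    def test_negative_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert strict_clock_divergence(-0.01, 1e-9) == 0.0

    def test_net_divergence_between_fixture_clades(self, cp_collapsed, cp_label_map):
        col, table = cp_collapsed
        ids = col.haplotype_ids
        clade = [cp_label_map["H3"], cp_label_map["H6"]]
        counts = table.total_counts
        in_clade = np.array([counts[h] if h in clade else 0 for h in ids])
        out_clade = np.array([0 if h in clade else counts[h] for h in ids])
        d_net = net_divergence_per_site(in_clade, out_clade, col.distances, 1531)
        assert d_net > 0
        t = strict_clock_divergence(d_net, 2e-9)
        assert t > 0
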