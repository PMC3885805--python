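"""Run-length histograms, pooling, and the exponential-function vs
exponential-distribution (geometric) fits."""

import numpy as np
import pytest

from seqchoice import (
    GeneratorSpec,
    RunLengthHistogram,
    compare_fits,
    fit_exp_distribution,
    fit_exp_function,
    generate,
    geometric_pmf,
    parse_sequence,
    pool_histograms,
    run_lengths,
)


class TestRunSegmentation:
    def test_worked_example_runs(self, worked_sequence):
        # S | AAA | S | A | S | A | SS
        h = run_lengths(worked_sequence)
        assert h.n_runs == 7
        assert dict(zip(h.lengths.tolist(), h.counts.tolist())) == {1: 5, 2: 1, 3: 1}

    def test_single_run(self):
        h = run_lengths(parse_sequence("AAAA"))
        assert h.n_runs == 1
        assert h.counts.tolist() == [0, 0, 0, 1]

    def test_perfect_alternation(self):
        h = run_lengths(parse_sequence("ASAS"))
        assert h.n_runs == 4
        assert h.counts.tolist() == [4]

    def test_exclude_censored_drops_final_run(self, worked_sequence):
        h = run_lengths(worked_sequence, include_censored=False)
        # final SS run dropped
        assert h.n_runs == 6
        assert dict(zip(h.lengths.tolist(), h.counts.tolist())) == {1: 5, 2: 0, 3: 1}

    def test_rel_freq_sums_to_one(self, worked_sequence):
        h = run_lengths(worked_sequence)
        assert h.rel_freq.sum() == pytest.approx(1.0, abs=1e-12)


class TestPooling:
    def test_pool_of_one_is_identity(self, worked_sequence):
        h = run_lengths(worked_sequence)
        for mode in ("sum", "mean_rel_freq"):
            pooled = pool_histograms([h], mode=mode)
            assert np.allclose(pooled.rel_freq, h.rel_freq)
            assert pooled.n_runs == h.n_runs

    def test_two_identical_mean_mode(self, worked_sequence):
        h = run_lengths(worked_sequence)
        pooled = pool_histograms([h, h], mode="mean_rel_freq")
        assert np.allclose(pooled.rel_freq, h.rel_freq)
        assert pooled.pooled_over == 2

    def test_sum_mode_arithmetic(self):
        h1 = RunLengthHistogram.from_run_list([1, 1])  # counts {1:2}
        h2 = RunLengthHistogram.from_run_list([2, 2])  # counts {2:2}
        pooled = pool_histograms([h1, h2], mode="sum")
        assert pooled.rel_freq.tolist() == [0.5, 0.5]

    def test_modes_differ_for_unequal_subjects(self):
        h1 = RunLengthHistogram.from_run_list([1] * 9 + [2])  # 90% length-1
        h2 = RunLengthHistogram.from_run_list([2])  # one run
        by_sum = pool_histograms([h1, h2], mode="sum")
        by_mean = pool_histograms([h1, h2], mode="mean_rel_freq")
        assert by_sum.rel_freq[0] == pytest.approx(9 / 11)
        assert by_mean.rel_freq[0] == pytest.approx(0.45)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pool_histograms([])

    def test_csv_roundtrip(self, tmp_path, worked_sequence):
        h = run_lengths(worked_sequence)
        path = tmp_path / "hist.csv"
        h.to_csv(path)
        back = RunLengthHistogram.from_csv(path)
        assert np.allclose(back.rel_freq, h.rel_freq)
        assert back.n_runs == h.n_runs


class TestExponentialFunctionFit:
    def test_noiseless_recovery(self):
        k = np.arange(1, 7)
        f = 0.6 * np.exp(-0.8 * k)
        h = RunLengthHistogram(k, f * 1000, f, n_runs=1000)
        res = fit_exp_function(h)
        assert res.params["a"] == pytest.approx(0.6, abs=1e-6)
        assert res.params["b"] == pytest.approx(0.8, abs=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_data_r_squared_not_applicable(self):
        k = np.arange(1, 5)
        f = np.full(4, 0.25)
        h = RunLengthHistogram(k, f * 100, f, n_runs=100)
        res = fit_exp_function(h)
        assert abs(res.params["b"]) < 1e-4
        assert res.r_squared is None

    def test_single_support_point_rejected(self):
        h = RunLengthHistogram.from_run_list([3, 3, 3])
        with pytest.raises(ValueError, match="support"):
            fit_exp_function(h)


class TestGeometricDistributionFit:
    def test_lambda_to_p_mapping(self):
        # decay constant 0.826 corresponds to switch prob ~0.56
        assert 1 - np.exp(-0.826) == pytest.approx(0.5622, abs=5e-4)

    def test_ml_recovery_from_geometric_runs(self, rng):
        lengths = rng.geometric(0.5, size=100_000)
        h = RunLengthHistogram.from_run_list(lengths)
        res = fit_exp_distribution(h, method="ml")
        assert res.params["p"] == pytest.approx(0.5, abs=0.01)

    def test_ml_estimator_is_reciprocal_mean(self):
        h = RunLengthHistogram.from_run_list([1, 2, 3, 2])  # mean 2
        res = fit_exp_distribution(h, method="ml")
        assert res.params["p"] == pytest.approx(0.5)

    def test_degenerate_single_short_run(self):
        h = RunLengthHistogram.from_run_list([1])
        res = fit_exp_distribution(h)
        assert res.params["p"] == pytest.approx(1.0, abs=1e-6)

    def test_fitted_mass_is_normalized(self):
        h = RunLengthHistogram.from_run_list([1, 1, 2, 3, 1, 2])
        res = fit_exp_distribution(h)
        lam = res.params["lambda"]
        k = np.arange(1, 2000)
        mass = (1 - np.exp(-lam)) * np.exp(-lam * (k - 1))
        assert mass.sum() == pytest.approx(1.0, abs=1e-9)


class TestGeometricPmf:
    @pytest.mark.parametrize(
        "p,k,expected", [(0.5, 1, 0.5), (1.0, 3, 0.0), (0.56, 1, 0.56)]
    )
    def test_values(self, p, k, expected):
        assert geometric_pmf(p, k) == pytest.approx(expected)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            geometric_pmf(0.0, 1)
        with pytest.raises(ValueError):
            geometric_pmf(0.5, 0)

    def test_discretization_identity(self):
        # integral of lam*exp(-lam*x) over (k-1, k] equals the geometric pmf
        # with p = 1 - exp(-lam)
        for lam in (0.1, 0.826, 2.5):
            p = 1 - np.exp(-lam)
            for k in range(1, 20):
                integral = np.exp(-lam * (k - 1)) - np.exp(-lam * k)
                assert abs(integral - geometric_pmf(p, k)) < 1e-12


class TestCompareFits:
    def test_geometric_data_both_fits_near_perfect(self):
        seq = generate(GeneratorSpec("markov", 10_000, 11, {"switch": 0.6}))
        cmp = compare_fits(run_lengths(seq, include_censored=False))
        assert cmp.exp_function.r_squared > 0.99
        assert cmp.exp_distribution.r_squared > 0.99
        assert np.abs(cmp.residuals_distribution).max() < 0.02

    def test_two_param_fit_never_worse(self):
        for seed, s in [(0, 0.3), (1, 0.5), (2, 0.56), (3, 0.7)]:
            seq = generate(GeneratorSpec("markov", 5000, seed, {"switch": s}))
            h = run_lengths(seq, include_censored=False)
            if len(h.support) < 3:
                continue
            cmp = compare_fits(h)
            assert cmp.exp_function.r_squared >= cmp.exp_distribution.r_squared - 1e-9

    def test_short_run_inflation_underestimated(self, rng):
        # 80% geometric(0.5) + 20% extra alternations: the one-parameter
        # distribution cannot track the inflated k=1 frequency
        base = rng.geometric(0.5, size=8000)
        inflated = np.concatenate([base, np.ones(2000, dtype=int)])
        h = RunLengthHistogram.from_run_list(inflated)
        cmp = compare_fits(h, distribution_method="ml")
        assert cmp.underestimates[0]  # k=1 observed above the fitted mass
        assert cmp.residuals_distribution[0] > 0.01
        # under least squares the single parameter chases k=1 instead and the
        # misfit surfaces as an overestimate of k=2
        cmp_ls = compare_fits(h)
        assert cmp_ls.residuals_distribution[1] < -0.01

    def test_pool_of_one_geometric_histogram_residuals_negligible(self):
        lam = 0.7
        k = np.arange(1, 15)
        f = (1 - np.exp(-lam)) * np.exp(-lam * (k - 1))
        f = f / f.sum()
        h = pool_histograms([RunLengthHistogram(k, f * 1e4, f, n_runs=10_000)])
        cmp = compare_fits(h)
        assert np.abs(cmp.residuals_distribution).max() < 1e-3
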