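"""Phi, Fisher, permutation Spearman, Marascuilo, temporal split, log-log."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alosaedna.fieldstats import (
    detection_rate_tables,
    fisher_exact_2x2,
    loglog_regression,
    marascuilo,
    phi_coefficient,
    spearman_with_permutation,
    temporal_split_test,
)


class TestPhi:
    def test_perfect_agreement(self):
        assert phi_coefficient([[10, 0], [0, 10]]) == pytest.approx(1.0)

    def test_independence(self):
        assert phi_coefficient([[5, 5], [5, 5]]) == pytest.approx(0.0)

    def test_equals_pearson_on_expanded_binaries(self):
        # oracle: expand the table into 100 paired 0/1 vectors and
        # correlate with scipy
        a, b, c, d = 30, 20, 10, 40
        x = np.repeat([1, 1, 0, 0], [a, b, c, d])
        y = np.repeat([1, 0, 1, 0], [a, b, c, d])
        pearson = stats.pearsonr(x, y).statistic
        assert phi_coefficient([[a, b], [c, d]]) == pytest.approx(
            pearson, abs=1e-12)

    @pytest.mark.parametrize("table", [
        [[3, 17], [9, 41]], [[1, 2], [3, 4]], [[50, 1], [2, 60]],
    ])
    def test_oracle_equivalence_parametrized(self, table):
        (a, b), (c, d) = table
        x = np.repeat([1, 1, 0, 0], [a, b, c, d])
        y = np.repeat([1, 0, 1, 0], [a, b, c, d])
        assert phi_coefficient(table) == pytest.approx(
            stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_zero_margin_undefined(self):
        with pytest.raises(ValueError, match="margin"):
            phi_coefficient([[5, 5], [0, 0]])


class TestFisher:
    def test_minimal_table_enumeration(self):
        # margins (1,1),(1,1): both tables have probability 0.5, so the
        # two-sided p sums to 1
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_transposition_invariance(self):
        t = [[46, 12], [26, 37]]
        p = fisher_exact_2x2(t)
        assert fisher_exact_2x2(np.transpose(t)) == pytest.approx(p)
        assert fisher_exact_2x2([[37, 26], [12, 46]]) == pytest.approx(p)
        assert 0 < p <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestSpearmanPermutation:
    def test_monotone_data_maximal(self):
        x = np.arange(20.0)
        res = spearman_with_permutation(x, x ** 2, n_perm=200, seed=1)
        assert res.rho == pytest.approx(1.0)
        assert res.p_permutation == pytest.approx(1 / 201)

    def test_antitone_data(self):
        x = np.arange(10.0)
        res = spearman_with_permutation(x, -x, n_perm=100, seed=1)
        assert res.rho == pytest.approx(-1.0)

    def test_exact_small_n_p_matches_enumeration(self):
        # n=6 tie-free: enumeration of all 720 rank permutations
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        res = spearman_with_permutation(x, y, n_perm=10, seed=0)
        from itertools import permutations
        rho_obs = stats.spearmanr(x, y).statistic
        count = sum(
            abs(stats.spearmanr(x, list(p)).statistic) >= abs(rho_obs) - 1e-12
            for p in permutations(y))
        assert res.p_analytic == pytest.approx(count / math.factorial(6))

    def test_rho_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, size=60).astype(float)
        y = x + rng.integers(0, 3, size=60)
        res = spearman_with_permutation(x, y, n_perm=50, seed=2)
        assert res.rho == pytest.approx(stats.spearmanr(x, y).statistic,
                                        abs=1e-12)

    def test_permutation_p_converges_to_analytic(self):
        # tie-free data: at large n_perm the permutation p approaches
        # the analytic value within Monte-Carlo error
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = spearman_with_permutation(x, y, n_perm=100_000, seed=5)
        mc_se = 3 * math.sqrt(res.p_analytic * (1 - res.p_analytic) / 100_000)
        assert abs(res.p_permutation - res.p_analytic) < mc_se + 1e-4

    def test_constant_vector_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_with_permutation(np.ones(10), np.arange(10.0))

    def test_null_distribution_returned_for_plotting(self):
        res = spearman_with_permutation(np.arange(10.0),
                                        np.arange(10.0)[::-1].copy(),
                                        n_perm=77, seed=0)
        assert res.null_distribution.shape == (77,)


class TestMarascuilo:
    def test_identical_proportions_never_significant(self):
        groups = {f"r{i}": (20, 100) for i in range(4)}
        table = marascuilo(groups)
        assert len(table) == 6  # k=4 -> 6 pairwise comparisons
        assert not table["significant"].any()

    def test_worked_example_with_chi_square_critical(self):
        # k=3 at alpha=0.05: chi2_{0.95,2}=5.991; pair (90/100, 10/100)
        # has range sqrt(5.991)*sqrt(0.09/100+0.09/100) ~ 0.104 << 0.8
        groups = {"a": (90, 100), "b": (10, 100), "c": (50, 100)}
        table = marascuilo(groups).set_index(["group_a", "group_b"])
        row = table.loc[("a", "b")]
        assert row["statistic"] == pytest.approx(0.8)
        expected_range = math.sqrt(stats.chi2.ppf(0.95, 2)) * math.sqrt(
            2 * 0.9 * 0.1 / 100)
        assert row["critical_range"] == pytest.approx(expected_range, rel=1e-9)
        assert row["significant"]

    def test_k2_matches_chi_square_two_proportion_decision(self):
        # with k=2 the procedure reduces to a chi-square-based
        # two-proportion test at the same alpha
        for (h1, n1), (h2, n2) in [((30, 100), (50, 100)),
                                   ((40, 100), (45, 100))]:
            table = marascuilo({"a": (h1, n1), "b": (h2, n2)}, alpha=0.05)
            p1, p2 = h1 / n1, h2 / n2
            z = abs(p1 - p2) / math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
            chi_decision = z ** 2 > stats.chi2.ppf(0.95, 1)
            assert bool(table["significant"].iloc[0]) == chi_decision

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            marascuilo({"only": (1, 10)})


def _survey_frame(dates, species, copies):
    return pd.DataFrame({
        "date": dates, "species_call": species, "edna_copies": copies,
        "edna_detected": [c is not None and not (isinstance(c, float)
                                                 and math.isnan(c))
                          for c in copies],
    })


class TestTemporalSplit:
    def test_strong_seasonal_contrast_detected(self, rng):
        n = 30
        dates = (["2015-03-20"] * n) + (["2015-05-05"] * n)
        copies = list(rng.lognormal(8, 1, n)) + list(rng.lognormal(4, 1, n))
        df = _survey_frame(dates, ["alewife"] * 2 * n, copies)
        res = temporal_split_test(df)
        assert res["alewife"]["p"] < 0.05
        assert res["alewife"]["median_early"] > res["alewife"]["median_late"]

    def test_power_and_null_rates(self, rng):
        # power: lognormal(high) early vs lognormal(low) late at n=30/30
        # should reject in at least 95% of simulations; identical
        # distributions should reject at about the nominal 5% rate
        n_sim, n = 500, 30
        dates = (["2015-03-20"] * n) + (["2015-05-05"] * n)
        hits_alt = hits_null = 0
        for _ in range(n_sim):
            early = rng.lognormal(8, 1, n)
            late_alt = rng.lognormal(6.5, 1, n)
            u, p = stats.mannwhitneyu(early, late_alt, alternative="two-sided")
            hits_alt += p < 0.05
            u, p = stats.mannwhitneyu(rng.lognormal(8, 1, n),
                                      rng.lognormal(8, 1, n),
                                      alternative="two-sided")
            hits_null += p < 0.05
        assert hits_alt / n_sim >= 0.95
        assert 0.02 <= hits_null / n_sim <= 0.09

    def test_boundary_date_counts_as_early(self):
        dates = ["2015-04-15"] * 3 + ["2015-04-16"] * 3
        df = _survey_frame(dates, ["alewife"] * 6, [10.0, 20, 30, 1.0, 2, 3])
        res = temporal_split_test(df)
        assert res["alewife"]["n_early"] == 3
        assert res["alewife"]["n_late"] == 3

    def test_sparse_period_skipped_with_warning(self):
        df = _survey_frame(["2015-03-20", "2015-05-05"], ["alewife"] * 2,
                           [10.0, 20.0])
        with pytest.warns(UserWarning, match="skipped"):
            assert temporal_split_test(df) == {}


class TestDetectionRates:
    def _records(self):
        return pd.DataFrame({
            "date": ["2015-04-01"] * 10,
            "shore": ["eastern"] * 5 + ["western"] * 5,
            "river": ["Choptank"] * 5 + ["James"] * 5,
            "edna_detected": [True, True, True, False, False,
                              True, False, False, False, False],
            "species_call": ["alewife", "alewife", "blueback", "", "",
                             "blueback", "", "", "", ""],
        })

    def test_single_year_rates(self):
        res = detection_rate_tables(self._records(), "year")
        rates = res["rates"]
        assert len(rates) == 1
        assert rates.loc[0, "hits"] == 4
        assert rates.loc[0, "n"] == 10
        assert rates.loc[0, "proportion"] == pytest.approx(0.4)
        assert res["fisher_p"] is None

    def test_two_group_fisher_attached(self):
        res = detection_rate_tables(self._records(), "shore")
        assert res["fisher_p"] == pytest.approx(
            fisher_exact_2x2([[3, 2], [1, 4]]))

    def test_species_by_shore_published_counts(self):
        rows = []
        for call, shore, k in [("alewife", "eastern", 46),
                               ("blueback", "eastern", 12),
                               ("alewife", "western", 26),
                               ("blueback", "western", 37)]:
            rows += [{"date": "2015-04-01", "shore": shore, "river": "",
                      "edna_detected": True, "species_call": call}] * k
        res = detection_rate_tables(pd.DataFrame(rows), "species_by_shore")
        assert res["fisher_p"] == pytest.approx(2.0823e-05, rel=1e-3)

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            detection_rate_tables(self._records(), "moon_phase")


class TestLogLogRegression:
    def test_identity_relation(self):
        c = np.geomspace(1, 1e4, 20)
        res = loglog_regression(c, c)
        assert res.slope == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_square_relation_has_slope_half(self):
        # copies = counts^2 -> log10(copies) = 2 log10(counts); regressing
        # copies on counts gives slope 2
        counts = np.geomspace(1, 100, 15)
        res = loglog_regression(counts ** 2, counts)
        assert res.slope == pytest.approx(2.0)

    def test_zeros_dropped_by_default(self):
        copies = np.array([0.0, 10, 100, 1000])
        counts = np.array([5.0, 1, 10, 100])
        res = loglog_regression(copies, counts)
        assert res.n == 3

    def test_r2_sampling_distribution_near_population_value(self, rng):
        # log-linear relation with noise tuned so population R^2 = 0.4;
        # fitted R^2 should usually fall in a band around it
        slope, n_sim, n = 0.8, 300, 100
        var_signal = slope ** 2 * 1.0
        sigma = math.sqrt(var_signal * 0.6 / 0.4)
        inside = 0
        for _ in range(n_sim):
            logx = rng.normal(0, 1, n)
            logy = slope * logx + rng.normal(0, sigma, n)
            res = loglog_regression(10 ** logy, 10 ** logx)
            inside += 0.25 <= res.r2 <= 0.55
        assert inside / n_sim >= 0.90

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            loglog_regression([1.0, 0.0], [1.0, 2.0])
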