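"""Frequency tables, haplotype diversity, exact tests and logistic regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import fisher_exact as scipy_fisher

from beemito.popstats import (
    fisher_exact_mc,
    frequency_table,
    haplotype_diversity,
    lineage_group,
    logistic_presence_vs_longitude,
)

#: per-haplotype counts of the analysed population
STUDY_COUNTS = [989, 124, 2, 5, 3, 2, 1, 1, 2, 1, 1, 8, 3, 1]

#: year-by-mitotype-group contingency table (rows 2020/2021/2022)
YEAR_TABLE = np.array(
    [[80, 9, 3, 2], [511, 65, 6, 6], [398, 52, 4, 7]]
)


class TestDiversity:
    def test_single_category_has_zero_diversity(self):
        for corrected in (False, True):
            assert haplotype_diversity([1143], corrected=corrected).H == 0.0

    def test_two_singletons_corrected_is_one(self):
        assert haplotype_diversity([1, 1], corrected=True).H == pytest.approx(1.0)

    def test_study_counts_round_to_printed_value(self):
        res = haplotype_diversity(STUDY_COUNTS, corrected=False)
        assert res.N == 1143 and res.k == 14
        assert res.H == pytest.approx(0.2394, abs=5e-5)
        assert round(res.H, 3) == 0.239
        corrected = haplotype_diversity(STUDY_COUNTS, corrected=True)
        assert round(corrected.H, 3) == 0.240

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(STUDY_COUNTS)
            assert haplotype_diversity(perm).H == pytest.approx(
                haplotype_diversity(STUDY_COUNTS).H
            )

    def test_uniform_scaling_invariance_when_uncorrected(self):
        h1 = haplotype_diversity(STUDY_COUNTS).H
        h10 = haplotype_diversity([10 * c for c in STUDY_COUNTS]).H
        assert h10 == pytest.approx(h1)

    def test_merging_categories_never_increases_h(self):
        full = haplotype_diversity(STUDY_COUNTS).H
        grouped = haplotype_diversity([989, 126, 13, 15]).H
        assert grouped <= full

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            haplotype_diversity([0, 0])


class TestFrequencyTable:
    def _records(self, rows):
        return pd.DataFrame(rows)

    def test_lineage_grouping_rules(self):
        assert lineage_group("C1", "C") == "C1"
        assert lineage_group("C2", "C") == "C2"
        assert lineage_group("C2c", "C") == "C2"
        assert lineage_group("M79", "M") == "M"
        assert lineage_group("A2w", "A") == "A"

    def test_study_truth_reproduces_year_table(self, study_population):
        table = frequency_table(
            study_population.truth, by="year", level="lineage-grouped"
        )
        assert table.strata == (2020, 2021, 2022)
        assert table.categories == ("C1", "C2", "M", "A")
        assert (table.counts == YEAR_TABLE).all()

    def test_single_record(self):
        df = self._records(
            [{"haplotype": "C1", "lineage": "C", "year": 2020}]
        )
        table = frequency_table(df, by="year")
        assert table.counts.tolist() == [[1]]
        assert table.to_frame(frequencies=True).iloc[0, 0] == 1.0

    def test_identical_strata_give_identical_rows(self):
        rows = []
        for year in (2020, 2021):
            rows += [
                {"haplotype": h, "lineage": l, "year": year}
                for h, l in [("C1", "C")] * 3 + [("M3", "M")] * 2
            ]
        table = frequency_table(self._records(rows), by="year")
        assert (table.counts[0] == table.counts[1]).all()

    def test_unknown_stratum_field_rejected(self):
        df = self._records([{"haplotype": "C1", "lineage": "C", "year": 2020}])
        with pytest.raises(ValueError):
            frequency_table(df, by="region")


def exhaustive_2x2_p(table):
    """Independent oracle: enumerate every table with the observed margins."""
    from math import comb

    (a, b), (c, d) = table
    r0, c0, n = a + b, a + c, a + b + c + d
    denominator = comb(n, r0)
    probs = {
        k: comb(c0, k) * comb(n - c0, r0 - k) / denominator
        for k in range(max(0, r0 - (n - c0)), min(r0, c0) + 1)
    }
    observed = probs[a]
    return sum(p for p in probs.values() if p <= observed * (1 + 1e-12))


class TestFisher:
    def test_diagonal_2x2_matches_full_enumeration(self):
        res = fisher_exact_mc([[5, 0], [0, 5]])
        assert res.method == "fisher-exact"
        assert res.p_value == pytest.approx(2 / 252)
        assert res.p_value == pytest.approx(exhaustive_2x2_p([[5, 0], [0, 5]]))

    @pytest.mark.parametrize(
        "table",
        [[[5, 0], [0, 5]], [[10, 5], [3, 12]], [[2, 7], [9, 1]], [[6, 6], [6, 6]]],
    )
    def test_2x2_exact_path_agrees_with_scipy(self, table):
        ours = fisher_exact_mc(table).p_value
        assert ours == pytest.approx(scipy_fisher(table).pvalue, rel=1e-9)

    def test_identical_rows_are_unremarkable(self):
        assert fisher_exact_mc([[10, 5], [10, 5]]).p_value >= 0.99

    @pytest.mark.parametrize("table", [[[5, 0], [0, 5]], [[10, 5], [3, 12]]])
    def test_mc_agrees_with_exact_within_3_standard_errors(self, table):
        exact = fisher_exact_mc(table).p_value
        n = 20_000
        mc = fisher_exact_mc(table, n_resamples=n, seed=5, method="mc").p_value
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(mc - exact) <= 3 * se + 1 / n

    def test_across_year_table_shows_no_differentiation(self):
        res = fisher_exact_mc(YEAR_TABLE, n_resamples=100_000, seed=7)
        assert res.method == "fisher-mc"
        assert res.p_value > 0.20

    def test_zero_row_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            res = fisher_exact_mc([[5, 5], [0, 0], [5, 5]], n_resamples=10_000, seed=1)
        assert res.p_value > 0.5

    def test_mc_requires_seed_and_enough_resamples(self):
        table = [[5, 1, 3], [2, 6, 1], [4, 4, 4]]
        with pytest.raises(ValueError):
            fisher_exact_mc(table, n_resamples=100_000, seed=None)
        with pytest.raises(ValueError):
            fisher_exact_mc(table, n_resamples=100, seed=1)


def _logistic_records(x, y):
    return pd.DataFrame(
        {
            "haplotype": np.where(y == 1, "A1a", "C1"),
            "lineage": np.where(y == 1, "A", "C"),
            "longitude": x,
        }
    )


class TestLogistic:
    def test_mirror_design_gives_null_slope(self):
        # outcome split identically at both longitudes: exact independence
        x = np.array([10.0] * 20 + [12.0] * 20)
        y = np.array(([0] * 10 + [1] * 10) * 2)
        res = logistic_presence_vs_longitude(_logistic_records(x, y), "A")
        assert res.slope == pytest.approx(0.0, abs=1e-6)
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-4)

    def test_slope_recovery_at_n_2000(self):
        rng = np.random.default_rng(123)
        beta = 1.5
        x = rng.uniform(9.2, 12.8, size=2000)
        p = expit(beta * (x - x.mean()))
        y = (rng.uniform(size=2000) < p).astype(int)
        res = logistic_presence_vs_longitude(_logistic_records(x, y), "A")
        assert abs(res.slope - beta) <= 0.2
        assert res.p_value < 1e-6

    def test_complete_separation_is_flagged(self):
        df = _logistic_records(np.array([9.5, 12.5]), np.array([0, 1]))
        res = logistic_presence_vs_longitude(df, "A")
        assert res.separation
        assert res.p_value is None

    def test_single_class_outcome_rejected(self):
        df = _logistic_records(np.array([9.5, 12.5]), np.array([0, 0]))
        with pytest.raises(ValueError):
            logistic_presence_vs_longitude(df, "A")

    def test_chi2_invariant_under_affine_longitude_rescaling(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(9.2, 12.8, size=400)
        y = (rng.uniform(size=400) < expit(0.8 * (x - 11))).astype(int)
        res1 = logistic_presence_vs_longitude(_logistic_records(x, y), "A")
        res2 = logistic_presence_vs_longitude(
            _logistic_records(10 * x - 3, y), "A"
        )
        assert res1.chi2 == pytest.approx(res2.chi2, rel=1e-6)
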