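"""Stratified tables, SMR, statistical tests — with closed-form oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from icu_intensity.analysis import (
    ALL_AGES,
    anova,
    chi_square_test,
    column_percentages,
    compute_smr,
    intensity_distribution,
    kruskal_wallis,
    mortality_by_group_and_age,
    mortality_table_from_counts,
    round_half_away,
    run_full_analysis,
)
from icu_intensity.filters import AGE_BANDS
from icu_intensity.fixtures import REFERENCE_TOTAL_STAYS, reference_stratum_table

# printed reference percentages: group -> [six age bands..., all ages]
PRINTED_MORTALITY_PCT = {
    0: [2.5, 7.8, 9.0, 12.6, 14.8, 21.3, 10.1],
    1: [3.9, 10.1, 18.7, 23.7, 30.4, 45.5, 15.6],
    2: [7.9, 13.7, 18.3, 20.6, 26.9, 40.3, 19.3],
    3: [30.2, 44.6, 54.1, 55.2, 61.2, 66.2, 50.7],
}

# printed reference column percentages of the intensity-by-age table
PRINTED_INTENSITY_PCT = {
    "<40": [35.6, 20.0, 13.4, 31.0],
    "40-59": [29.7, 13.1, 13.8, 43.4],
    "60-69": [28.5, 10.8, 13.3, 47.4],
    "70-74": [28.8, 10.4, 14.1, 46.6],
    "75-79": [30.1, 9.5, 12.7, 47.7],
    ">=80": [33.5, 8.3, 14.3, 43.9],
}

PRINTED_BINARY_PCT = {"<80": [30.5, 13.2, 13.5, 42.7], ">=80": [33.5, 8.3, 14.3, 43.9]}


def test_round_half_away():
    assert round_half_away(0.05) == 0.1
    assert round_half_away(2.25) == 2.3
    assert round_half_away(-2.25) == -2.3
    assert round_half_away(10.14) == 10.1
    assert round_half_away(31.0, 0) == 31.0


class TestSmr:
    def test_trivial_ratios(self):
        assert compute_smr(10, 10)[0] == 1.0
        assert compute_smr(20, 10)[0] == 2.0

    def test_exact_poisson_interval(self):
        # Garwood 95% interval for an observed count of 10: (4.795, 18.390)
        _, (low, high) = compute_smr(10, 10.0)
        assert low == pytest.approx(0.4795, abs=2e-4)
        assert high == pytest.approx(1.8390, abs=2e-4)

    def test_zero_observed_has_zero_lower_limit(self):
        smr, (low, high) = compute_smr(0, 5.0)
        assert smr == 0.0 and low == 0.0 and high > 0

    def test_undefined_when_no_expected_deaths(self):
        with pytest.raises(ValueError):
            compute_smr(3, 0.0)

    def test_recovers_known_multiplier_on_synthetic_stratum(self):
        """SMR estimate on a cohort generated with multiplier 1.5 ≈ 1.5."""
        from icu_intensity.filters import apply_inclusion
        from icu_intensity.intensity import classify_frame
        from icu_intensity.saps2 import score_frame
        from icu_intensity.simulate import (
            SimulationConfig,
            generate_cohort,
            true_death_probability,
        )

        config = SimulationConfig(n_stays=20_000, seed=314).with_multipliers(
            {f"{band}:{group}": 1.5 for band in AGE_BANDS for group in range(4)}
        )
        cohort = generate_cohort(config)
        included, _ = apply_inclusion(classify_frame(score_frame(cohort)))
        q = true_death_probability(included, config)
        expected = included["predicted_mortality"].sum()
        truth = q.sum() / expected  # exact ground truth (≤ 1.5 if clamped)
        smr, _ = compute_smr(int(included["hospital_death"].sum()), expected)
        se = np.sqrt(np.sum(q * (1 - q))) / expected
        assert abs(smr - truth) < 3 * se
        # clamping min(1, m·p) attenuates the nominal multiplier for the
        # sickest stays, so the exact ground truth lies below 1.5
        assert 1.2 < truth <= 1.5


class TestChiSquare:
    def test_no_association(self):
        result = chi_square_test([[10, 10], [10, 10]])
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(1.0)
        assert result.df == 1

    def test_matches_hand_pearson_formula_on_reference_counts(self):
        # group-3 deaths/survivors among <80 vs ≥80 from the printed counts
        table = np.array([[4197, 4504], [931, 476]], dtype=float)
        result = chi_square_test(table)
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        oracle = float(((table - expected) ** 2 / expected).sum())
        assert result.statistic == pytest.approx(oracle, rel=1e-12)
        assert result.df == 1
        assert result.p_value < 0.001

    def test_doubling_cells_doubles_statistic(self):
        table = np.array([[12, 30], [40, 18]], dtype=float)
        single = chi_square_test(table).statistic
        double = chi_square_test(2 * table).statistic
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_brute_force_expected_counts_on_random_tables(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            r, c = rng.integers(2, 6, size=2)
            table = rng.integers(5, 80, size=(r, c)).astype(float)
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
            oracle = float(((table - expected) ** 2 / expected).sum())
            result = chi_square_test(table)
            assert result.statistic == pytest.approx(oracle, rel=1e-10)
            assert result.df == (r - 1) * (c - 1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [5, 5]])


class TestRankAndVarianceTests:
    def test_identical_groups_degenerate(self):
        assert kruskal_wallis([[2, 2, 2], [2, 2, 2]]).statistic == 0.0
        result = anova([[2, 2, 2], [2, 2, 2]])
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_kruskal_matches_rank_formula(self):
        # groups {1,2,3} and {4,5,6}: ranks 1..6, H = 12/(6·7)·(36/3+225/3) − 21
        result = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert result.statistic == pytest.approx(12 / 42 * (12 + 75) - 21, rel=1e-12)
        assert result.df == 1

    def test_anova_f_matches_closed_form(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [5.0, 5.0, 8.0]]
        flat = np.concatenate(groups)
        grand = flat.mean()
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        oracle = (ss_between / 2) / (ss_within / 6)
        result = anova(groups)
        assert result.statistic == pytest.approx(oracle, rel=1e-12)
        assert result.df == (2, 6)

    def test_group_requirements(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            anova([[1, 2], []])


class TestReferenceTables:
    """The printed stratum counts reproduce every printed percentage."""

    def test_marginals(self):
        strata = reference_stratum_table()
        assert int(strata["n"].sum()) == REFERENCE_TOTAL_STAYS
        group_sizes = strata.groupby("intensity_group")["n"].sum()
        assert group_sizes.tolist() == [7297, 2961, 3212, 10108]
        deaths = strata.groupby("intensity_group")["deaths"].sum()
        assert deaths.tolist() == [738, 461, 619, 5128]

    def test_mortality_percentages_reproduce_printed_values(self):
        table = mortality_table_from_counts(reference_stratum_table())
        for group, printed in PRINTED_MORTALITY_PCT.items():
            for label, expected in zip((*AGE_BANDS, ALL_AGES), printed):
                row = table[
                    (table["intensity_group"] == group) & (table["age_label"] == label)
                ]
                assert row["mortality_pct"].iloc[0] == expected, (group, label)

    def test_intensity_distribution_percentages_reproduce_printed_values(self):
        counts = intensity_distribution(reference_stratum_table(), "band")
        pct = column_percentages(counts)
        for band, expected in PRINTED_INTENSITY_PCT.items():
            assert pct[band].tolist() == expected, band
        assert counts[">=80"].tolist() == [1073, 266, 457, 1407]
        assert counts[">=80"].sum() == 3203

    def test_binary_distribution_percentages(self):
        counts = intensity_distribution(reference_stratum_table(), "binary")
        assert counts["<80"].tolist() == [6224, 2695, 2755, 8701]
        pct = column_percentages(counts)
        for col, expected in PRINTED_BINARY_PCT.items():
            assert pct[col].tolist() == expected, col


@pytest.fixture(scope="module")
def analyzed():
    from icu_intensity.filters import apply_inclusion
    from icu_intensity.intensity import classify_frame
    from icu_intensity.saps2 import score_frame
    from icu_intensity.simulate import SimulationConfig, generate_cohort

    cohort = generate_cohort(SimulationConfig(n_stays=8000, seed=77))
    included, _ = apply_inclusion(classify_frame(score_frame(cohort)))
    return included


class TestCohortTables:

    def test_empty_cohort_gives_empty_table(self):
        assert len(mortality_by_group_and_age(pd.DataFrame())) == 0

    def test_marginal_conservation(self, analyzed):
        table = mortality_by_group_and_age(analyzed)
        all_ages = table[table["age_label"] == ALL_AGES]
        assert all_ages["n"].sum() == len(analyzed)
        assert all_ages["observed_deaths"].sum() == analyzed["hospital_death"].sum()
        bands = table[table["age_label"] != ALL_AGES]
        assert bands["n"].sum() == len(analyzed)
        counts = intensity_distribution(analyzed, "band")
        assert counts.to_numpy().sum() == len(analyzed)

    def test_distribution_invariant_under_permutation(self, analyzed):
        counts = intensity_distribution(analyzed, "band")
        shuffled = analyzed.sample(frac=1.0, random_state=0).reset_index(drop=True)
        pd.testing.assert_frame_equal(counts, intensity_distribution(shuffled, "band"))

    def test_single_record_cohort(self, analyzed):
        one = analyzed.iloc[[0]]
        counts = intensity_distribution(one, "band")
        assert counts.to_numpy().sum() == 1
        assert (counts.to_numpy() > 0).sum() == 1

    def test_full_report_smoke(self, analyzed):
        report = run_full_analysis(analyzed)
        assert report.n_stays == len(analyzed)
        assert 0 <= report.hospital_mortality_pct <= 100
        assert report.mortality_table["smr"].notna().all()
        low = report.mortality_table["smr_ci_low"]
        high = report.mortality_table["smr_ci_high"]
        assert (low <= report.mortality_table["smr"]).all()
        assert (report.mortality_table["smr"] <= high).all()
        assert set(report.tests) == {
            "intensity_by_age_chi2",
            "intensity_by_age_kruskal",
            "age_adjusted_saps2_by_age_anova",
        }
        assert report.tests["intensity_by_age_chi2"].p_value <= 1.0
        payload = report.to_dict()
        assert payload["n_stays"] == len(analyzed)

    def test_report_serialization(self, analyzed, tmp_path):
        report = run_full_analysis(analyzed)
        report.write_dir(tmp_path)
        for name in ("table2_counts.csv", "table2_pct.csv", "table3_counts.csv",
                     "table4_mortality.csv", "smr_by_age_group.csv", "report.json"):
            assert (tmp_path / name).exists()
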