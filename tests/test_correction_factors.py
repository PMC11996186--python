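import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aicm import brazil2015
from aicm.correction_factors import (
    ConfigurationError,
    DEFAULT_MISCARRIAGE_FACTORS,
    MiscarriageFactors,
    ScenarioSpec,
    UndefinedFactorError,
    apply_miscarriage,
    canonical_scenarios,
    restrict_to_survey_ages,
    run_scenario,
    scenario_suite,
)
from aicm.data_io import COARSE_BANDS, CountsTable


class TestApplyMiscarriage:
    def test_public_sector_corrected_rows(self):
        counts = brazil2015.sus_margins().to_national()
        out = apply_miscarriage(counts)
        assert dict(out.band_totals()) == {
            "10-29": 75_060, "30-39": 35_121, "40-49": 7_001,
        }
        assert out.total == 117_182

    def test_supplementary_corrected_rows_round_at_pooled_band(self):
        counts = brazil2015.ans_margins("icd_or_procedure")
        out = apply_miscarriage(counts)
        # 7,365 x 0.90 = 6,628.5 rounds up only when 10-19/20-29 are pooled
        assert dict(out.band_totals()) == {
            "10-29": 6_629, "30-39": 9_504, "40-49": 1_658,
        }
        assert out.total == 17_791

    def test_unit_factors_preserve_totals(self):
        counts = brazil2015.sus_margins()
        ident = MiscarriageFactors({b: 1.0 for b in COARSE_BANDS})
        assert apply_miscarriage(counts, ident).total == counts.total

    def test_missing_band_is_a_configuration_error(self):
        counts = CountsTable.from_dict({("BR", "40-49"): 10})
        partial = MiscarriageFactors({"10-19": 0.9})
        with pytest.raises(ConfigurationError, match="40-49"):
            apply_miscarriage(counts, partial)

    @settings(deadline=None, max_examples=60)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=10**5),
                        min_size=4, max_size=4),
        factors=st.lists(st.floats(min_value=0.05, max_value=1.0),
                         min_size=4, max_size=4),
    )
    def test_correction_never_increases_the_total(self, counts, factors):
        table = CountsTable.from_dict(
            {("BR", b): c for b, c in zip(COARSE_BANDS, counts)}
        )
        mf = MiscarriageFactors(
            {b: round(f, 2) for b, f in zip(COARSE_BANDS, factors)}
        )
        out = apply_miscarriage(table, mf, rounded=False)
        assert out.total <= table.total + 1e-9

    def test_total_decreases_monotonically_in_each_factor(self):
        table = brazil2015.ans_margins("icd_or_procedure")
        hi = MiscarriageFactors({"10-19": 0.9, "20-29": 0.9, "30-39": 0.85,
                                 "40-49": 0.75})
        lo = MiscarriageFactors({"10-19": 0.9, "20-29": 0.9, "30-39": 0.70,
                                 "40-49": 0.75})
        assert (apply_miscarriage(table, lo).total
                < apply_miscarriage(table, hi).total)


class TestRestrictToSurveyAges:
    def make_fine(self, c15, c20, c25, c30, c35):
        return CountsTable.from_dict(
            {("BR", "15-19"): c15, ("BR", "20-24"): c20, ("BR", "25-29"): c25,
             ("BR", "30-34"): c30, ("BR", "35-39"): c35}
        )

    def test_zero_share_uses_only_20_39_bands(self, sus_microdata):
        fine = self.make_fine(1000, 100, 100, 100, 100)
        _, supp0 = restrict_to_survey_ages(
            sus_microdata.iloc[:0], fine, share_18_19=0.0
        )
        expected = round(0.90 * 200 + 0.85 * 200)
        assert supp0 == expected

    def test_full_share_with_empty_15_19_band_matches_zero_share(
        self, sus_microdata
    ):
        fine = self.make_fine(0, 50, 50, 40, 40)
        empty_sus = sus_microdata.iloc[:0]
        _, a = restrict_to_survey_ages(empty_sus, fine, share_18_19=0.0)
        _, b = restrict_to_survey_ages(empty_sus, fine, share_18_19=1.0)
        assert a == b

    def test_national_microdata_reproduce_sector_totals(
        self, sus_microdata, ans_counts_fine
    ):
        hosp_sus, hosp_supp = restrict_to_survey_ages(
            sus_microdata, ans_counts_fine, year=brazil2015.YEAR
        )
        assert (hosp_sus, hosp_supp) == (103_623, 15_963)

    def test_coarse_private_counts_are_rejected(self, sus_microdata):
        coarse = brazil2015.ans_margins("icd_or_procedure")
        with pytest.raises(ConfigurationError, match="fine"):
            restrict_to_survey_ages(sus_microdata.iloc[:0], coarse)


HOSP_SUS, HOSP_SUPP = 103_623, 15_963


class TestRunScenario:
    def test_pooled_factor(self):
        spec = ScenarioSpec(name="1", pooled=True, pna_total=503_000)
        res = run_scenario(spec, HOSP_SUS, HOSP_SUPP)
        assert res.factor_total == 4.2
        assert res.factor_sus is None

    def test_sector_mode_equal_frequencies(self):
        spec = ScenarioSpec(
            name="2",
            pop_sus=brazil2015.SECTOR_POPULATION_18_39["sus"],
            pop_supp=brazil2015.SECTOR_POPULATION_18_39["supplementary"],
            freq_sus=0.0135, freq_supp=0.0135,
        )
        res = run_scenario(spec, HOSP_SUS, HOSP_SUPP)
        assert (res.est_abortions_sus, res.est_abortions_supp) == (371_208, 128_803)
        assert (res.factor_sus, res.factor_supp) == (3.6, 8.1)

    def test_constrained_mode_half_frequency(self):
        spec = ScenarioSpec(
            name="3a", freq_ratio=0.5, pna_total=503_000,
            pop_sus=brazil2015.SECTOR_POPULATION_18_39["sus"],
            pop_supp=brazil2015.SECTOR_POPULATION_18_39["supplementary"],
        )
        res = run_scenario(spec, HOSP_SUS, HOSP_SUPP)
        assert res.freq_sus == pytest.approx(0.0156, abs=5e-5)
        assert res.factor_supp == 4.7

    def test_constrained_with_unit_ratio_equals_pooled_frequency_sector_mode(self):
        pops = dict(pop_sus=2_000_000.0, pop_supp=1_000_000.0)
        total = 30_000
        constrained = run_scenario(
            ScenarioSpec(freq_ratio=1.0, pna_total=total, **pops), 5_000, 1_000
        )
        sector = run_scenario(
            ScenarioSpec(freq_sus=total / 3_000_000.0, **pops), 5_000, 1_000
        )
        assert constrained.factor_sus == sector.factor_sus
        assert constrained.factor_supp == sector.factor_supp

    def test_zero_hospitalizations_make_the_factor_undefined(self):
        spec = ScenarioSpec(pooled=True, pna_total=1000)
        with pytest.raises(UndefinedFactorError):
            run_scenario(spec, 0, 0)

    def test_incomplete_spec_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            run_scenario(ScenarioSpec(pooled=True), 1, 1)
        with pytest.raises(ConfigurationError):
            run_scenario(ScenarioSpec(freq_sus=0.01), 1, 1)


@pytest.fixture(scope="module")
def suite():
    return scenario_suite(canonical_scenarios(), HOSP_SUS, HOSP_SUPP)


class TestScenarioSuite:
    def test_five_canonical_rows(self, suite):
        assert suite["scenario"].tolist() == ["1", "2", "3a", "3b", "3c"]

    def test_public_sector_factor_column(self, suite):
        got = suite["factor_sus"].tolist()
        assert math.isnan(got[0])
        assert got[1:] == [3.6, 4.1, 3.9, 3.7]

    def test_supplementary_factor_column(self, suite):
        got = suite["factor_supp"].tolist()
        assert math.isnan(got[0])
        assert got[1:] == [8.1, 4.7, 6.5, 7.5]

    def test_constrained_estimates_match_published_within_a_tenth_percent(
        self, suite
    ):
        published = {
            "3a": (428_635, 74_365), "3b": (399_131, 103_869),
            "3c": (383_301, 119_699),
        }
        for name, (sus_exp, supp_exp) in published.items():
            row = suite[suite["scenario"] == name].iloc[0]
            assert abs(row.est_abortions_sus - sus_exp) / sus_exp < 1e-3
            assert abs(row.est_abortions_supp - supp_exp) / supp_exp < 1e-3

    def test_pooled_factor_lies_between_sector_factors(self, suite):
        pooled = suite.loc[suite["scenario"] == "1", "factor_total"].iloc[0]
        for _, row in suite[suite["scenario"] != "1"].iterrows():
            lo = min(row.factor_sus, row.factor_supp)
            hi = max(row.factor_sus, row.factor_supp)
            assert lo <= pooled <= hi

    def test_single_pooled_spec_gives_one_row(self):
        df = scenario_suite(
            [ScenarioSpec(pooled=True, pna_total=100.0)], 10, 10
        )
        assert len(df) == 1 and df["factor_total"].iloc[0] == 5.0
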