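import pytest

from aicm import brazil2015
from aicm.data_io import PanelTable
from aicm.estimation import (
    PipelineStageError,
    RunConfig,
    SectorInputs,
    abortion_rate,
    abortion_ratio,
    compute_estimates,
    estimate_abortions,
    full_pipeline,
    sector_denominators,
)


@pytest.fixture(scope="module")
def denominators():
    return sector_denominators(
        brazil2015.population_panel(), brazil2015.births_panel()
    )


class TestEstimateAbortions:
    def test_public_sector_point_and_bounds(self):
        inp = SectorInputs(117_182, 4, 3, 5, 1, 1)
        assert estimate_abortions(inp) == (468_728, 351_546, 585_910)

    def test_supplementary_point_and_bounds(self):
        inp = SectorInputs(17_791, 5, 4, 6, 1, 1)
        assert estimate_abortions(inp) == (88_955, 71_164, 106_746)

    def test_zero_factor_gives_zero(self):
        assert estimate_abortions(SectorInputs(1000, 0, 0, 0, 1, 1)) == (0, 0, 0)

    def test_bounds_must_bracket_the_point(self):
        with pytest.raises(ValueError):
            SectorInputs(10, 4, 5, 6, 1, 1)


class TestSectorDenominators:
    def test_population_split(self, denominators):
        assert denominators.population_supp == 16_450_369
        assert denominators.population_sus == 47_418_584
        assert denominators.population_total == 63_868_953

    def test_live_birth_split(self, denominators):
        assert denominators.births_supp == 796_198
        assert denominators.births_sus == 2_221_005
        assert denominators.births_total == 3_017_203

    def test_zero_coverage_assigns_everything_to_the_public_sector(self):
        zero = {b: 0.0 for b in brazil2015.BAND_COVERAGE}
        den = sector_denominators(
            brazil2015.population_panel(), brazil2015.births_panel(), zero
        )
        assert den.population_supp == 0
        assert den.population_sus == den.population_total

    def test_missing_band_coverage_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            sector_denominators(
                brazil2015.population_panel(), brazil2015.births_panel(),
                {"10-19": 0.18},
            )


class TestIndicators:
    @pytest.mark.parametrize(
        "abortions,population,expected",
        [(557_683, 63_868_953, 8.7), (468_728, 47_418_584, 9.9), (0, 1000, 0.0)],
    )
    def test_rate_per_thousand_women(self, abortions, population, expected):
        assert abortion_rate(abortions, population) == expected

    @pytest.mark.parametrize(
        "abortions,births,expected",
        [(557_683, 3_017_203, 18.5), (468_728, 2_221_005, 21.1),
         (88_955, 796_198, 11.2)],
    )
    def test_ratio_per_hundred_live_births(self, abortions, births, expected):
        assert abortion_ratio(abortions, births) == expected

    def test_zero_denominators_are_errors(self):
        with pytest.raises(ZeroDivisionError):
            abortion_rate(10, 0)
        with pytest.raises(ZeroDivisionError):
            abortion_ratio(10, 0)


@pytest.fixture(scope="module")
def result(denominators):
    return compute_estimates(117_182, 17_791, denominators)


class TestComputeEstimates:
    def test_sector_and_total_abortions_with_bounds(self, result):
        assert (result.sus.abortions, result.sus.abortions_ll,
                result.sus.abortions_ul) == (468_728, 351_546, 585_910)
        assert (result.supplementary.abortions,
                result.supplementary.abortions_ll,
                result.supplementary.abortions_ul) == (88_955, 71_164, 106_746)
        assert (result.total.abortions, result.total.abortions_ll,
                result.total.abortions_ul) == (557_683, 422_710, 692_656)

    def test_rates(self, result):
        assert (result.sus.rate, result.sus.rate_ll, result.sus.rate_ul) == (
            9.9, 7.4, 12.4)
        assert (result.supplementary.rate, result.supplementary.rate_ll,
                result.supplementary.rate_ul) == (5.4, 4.3, 6.5)
        assert (result.total.rate, result.total.rate_ll,
                result.total.rate_ul) == (8.7, 6.6, 10.8)

    def test_ratios(self, result):
        assert (result.sus.ratio, result.sus.ratio_ll, result.sus.ratio_ul) == (
            21.1, 15.8, 26.4)
        assert (result.supplementary.ratio, result.supplementary.ratio_ll,
                result.supplementary.ratio_ul) == (11.2, 8.9, 13.4)
        assert (result.total.ratio, result.total.ratio_ll,
                result.total.ratio_ul) == (18.5, 14.0, 23.0)

    def test_sector_additivity_is_exact(self, result):
        assert result.total.abortions == (
            result.sus.abortions + result.supplementary.abortions
        )

    def test_widening_the_factor_range_widens_the_bounds(self, denominators):
        narrow = compute_estimates(
            117_182, 17_791, denominators,
            {"sus": (4, (4, 4)), "supplementary": (5, (5, 5))},
        )
        wide = compute_estimates(
            117_182, 17_791, denominators,
            {"sus": (4, (2, 6)), "supplementary": (5, (3, 7))},
        )
        assert wide.total.abortions_ll <= narrow.total.abortions_ll
        assert wide.total.abortions_ul >= narrow.total.abortions_ul
        assert wide.total.rate_ll <= narrow.total.rate_ll
        assert wide.total.rate_ul >= narrow.total.rate_ul

    def test_scaling_hospitalizations_scales_abortions(self, denominators):
        base = compute_estimates(1000, 500, denominators)
        triple = compute_estimates(3000, 1500, denominators)
        assert triple.total.abortions == 3 * base.total.abortions


@pytest.fixture(scope="module")
def config(dataset_dir):
    return RunConfig(
        sus_path=str(dataset_dir / "sus_admissions.csv"),
        ans_cons_path=str(dataset_dir / "ans_cons.csv"),
        ans_det_path=str(dataset_dir / "ans_det.csv"),
        population_path=str(dataset_dir / "population.csv"),
        births_path=str(dataset_dir / "births.csv"),
        beneficiaries_paths=[str(dataset_dir / "beneficiaries.csv")],
    )


@pytest.fixture(scope="module")
def pipeline_result(config):
    return full_pipeline(config)


class TestFullPipeline:
    def test_end_to_end_headline_indicators(self, pipeline_result):
        t = pipeline_result.estimate.total
        assert (t.rate, t.rate_ll, t.rate_ul) == (8.7, 6.6, 10.8)
        assert (t.ratio, t.ratio_ll, t.ratio_ul) == (18.5, 14.0, 23.0)
        assert t.abortions == 557_683

    def test_microdata_route_equals_fixture_aggregate_route(
        self, pipeline_result, denominators
    ):
        """Running on generated records reproduces the direct margin run."""
        direct = compute_estimates(117_182, 17_791, denominators)
        assert pipeline_result.estimate == direct

    def test_coverage_and_legacy_comparison(self, pipeline_result):
        assert pipeline_result.coverage_national_pct == 25.88
        assert pipeline_result.legacy_ratio_national == 1.72

    def test_scenario_table_attached(self, pipeline_result):
        assert pipeline_result.scenarios is not None
        assert pipeline_result.scenarios["factor_total"].iloc[0] == 4.2

    def test_manifest_records_inputs_and_parameters(self, pipeline_result):
        m = pipeline_result.manifest
        assert set(m) == {"inputs", "parameters", "counts"}
        assert len(m["inputs"]["sus"]) == 64  # sha256 hex digest
        assert m["parameters"]["year"] == 2015

    def test_missing_input_aborts_with_the_stage_name(self, config):
        import dataclasses

        broken = dataclasses.replace(config, sus_path="no/such/file.csv")
        with pytest.raises(PipelineStageError, match="read_sus"):
            full_pipeline(broken)
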