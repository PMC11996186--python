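"""Estimation equation, sensitivity bounds, and the rate/ratio indicators.

The induced-abortion estimate per funding sector is

    abortions = hospitalizations × miscarriage factor × complications factor

with the miscarriage factor already applied upstream per age band. Bounds
come from moving the complications factor one unit down (LL) and up (UL) —
the only uncertainty the method quantifies. Indicators are the abortion
rate per 1,000 women aged 10–49 and the abortion ratio per 100 live births,
with sector denominators obtained by splitting national panels with
band-level insurance coverages.

:func:`full_pipeline` wires every stage — reading, case selection, linkage,
corrections, optional scenario calibration, estimation — into one
reproducible run driven by a :class:`RunConfig`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import brazil2015
from .case_selection import SelectionRule, link_ans, select_ans, select_sus
from .correction_factors import (
    MiscarriageFactors,
    apply_miscarriage,
    canonical_scenarios,
    restrict_to_survey_ages,
    scenario_suite,
)
from .coverage import compute_coverage, estimated_reported_ratio, legacy_private_estimate
from .data_io import CountsTable, PanelTable, read_table, round_half_up

__all__ = [
    "SectorInputs",
    "SectorEstimate",
    "EstimateResult",
    "SectorDenominators",
    "RunConfig",
    "PipelineStageError",
    "estimate_abortions",
    "sector_denominators",
    "abortion_rate",
    "abortion_ratio",
    "compute_estimates",
    "full_pipeline",
]


# ---------------------------------------------------------------------------
# Core arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectorInputs:
    """Everything needed to estimate one sector's abortions and indicators."""

    hosp_corrected: int
    factor: int
    factor_ll: int
    factor_ul: int
    population_10_49: float
    live_births: float

    def __post_init__(self):
        if not self.factor_ll <= self.factor <= self.factor_ul:
            raise ValueError("factor bounds must bracket the point factor")
        if self.hosp_corrected < 0 or self.population_10_49 < 0 or self.live_births < 0:
            raise ValueError("counts must be non-negative")


def estimate_abortions(inputs: SectorInputs) -> tuple[int, int, int]:
    """Point estimate and (LL, UL) bounds: corrected count × factor."""
    return (
        inputs.hosp_corrected * inputs.factor,
        inputs.hosp_corrected * inputs.factor_ll,
        inputs.hosp_corrected * inputs.factor_ul,
    )


def abortion_rate(abortions: float, population: float) -> float:
    """Induced abortions per 1,000 women aged 10–49, to one decimal."""
    if population <= 0:
        raise ZeroDivisionError("abortion rate undefined for zero population")
    return round_half_up(abortions / population * 1_000, 1)


def abortion_ratio(abortions: float, live_births: float) -> float:
    """Induced abortions per 100 live births, to one decimal."""
    if live_births <= 0:
        raise ZeroDivisionError("abortion ratio undefined for zero live births")
    return round_half_up(abortions / live_births * 100, 1)


# ---------------------------------------------------------------------------
# Sector denominators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectorDenominators:
    population_total: float
    population_supp: float
    population_sus: float
    births_total: float
    births_supp: float
    births_sus: float


def _split(panel: PanelTable, band_coverage: Mapping[str, float]) -> tuple[float, float]:
    totals = panel.to_coarse().band_totals()
    supp = 0.0
    for band, n in totals.items():
        cov = band_coverage.get(band)
        if cov is None:
            raise ValueError(f"no coverage supplied for band {band}")
        if not 0 <= cov <= 1:
            raise ValueError(f"coverage for {band} outside [0, 1]: {cov}")
        supp += cov * float(n)
    total = float(totals.sum())
    supp = round_half_up(supp)
    return total, supp


def sector_denominators(
    population: PanelTable,
    births: PanelTable,
    band_coverage: Mapping[str, float] = brazil2015.BAND_COVERAGE,
) -> SectorDenominators:
    """Split national denominators into supplementary vs public sectors.

    The supplementary denominator is the coverage-weighted band sum (rounded
    half-up); the public one is defined as total minus supplementary, so the
    two always add up exactly.
    """
    pop_total, pop_supp = _split(population, band_coverage)
    b_total, b_supp = _split(births, band_coverage)
    return SectorDenominators(
        population_total=pop_total, population_supp=pop_supp,
        population_sus=pop_total - pop_supp,
        births_total=b_total, births_supp=b_supp, births_sus=b_total - b_supp,
    )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SectorEstimate:
    name: str
    hosp_corrected: int
    factor: int | None
    factor_ll: int | None
    factor_ul: int | None
    abortions: int
    abortions_ll: int
    abortions_ul: int
    population: float
    live_births: float
    rate: float
    rate_ll: float
    rate_ul: float
    ratio: float
    ratio_ll: float
    ratio_ul: float


@dataclass(frozen=True)
class EstimateResult:
    """Sector and total estimates with LL/UL on every quantity.

    The total abortions (and each bound) are sums of the sector values, so
    sector additivity holds exactly; total indicators use total
    denominators.
    """

    sus: SectorEstimate
    supplementary: SectorEstimate
    total: SectorEstimate

    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(s) for s in (self.sus, self.supplementary, self.total)]
        return pd.DataFrame(rows).set_index("name")


def _sector_estimate(
    name: str, inputs: SectorInputs
) -> SectorEstimate:
    point, ll, ul = estimate_abortions(inputs)
    return SectorEstimate(
        name=name,
        hosp_corrected=inputs.hosp_corrected,
        factor=inputs.factor, factor_ll=inputs.factor_ll, factor_ul=inputs.factor_ul,
        abortions=point, abortions_ll=ll, abortions_ul=ul,
        population=inputs.population_10_49, live_births=inputs.live_births,
        rate=abortion_rate(point, inputs.population_10_49),
        rate_ll=abortion_rate(ll, inputs.population_10_49),
        rate_ul=abortion_rate(ul, inputs.population_10_49),
        ratio=abortion_ratio(point, inputs.live_births),
        ratio_ll=abortion_ratio(ll, inputs.live_births),
        ratio_ul=abortion_ratio(ul, inputs.live_births),
    )


def compute_estimates(
    hosp_corrected_sus: int,
    hosp_corrected_supp: int,
    denominators: SectorDenominators,
    factors: Mapping[str, tuple[int, tuple[int, int]]] = brazil2015.COMPLICATION_FACTORS,
) -> EstimateResult:
    """Apply the estimation equation per sector and derive all indicators."""
    f_sus, (ll_sus, ul_sus) = factors["sus"]
    f_supp, (ll_supp, ul_supp) = factors["supplementary"]
    sus = _sector_estimate(
        "sus",
        SectorInputs(hosp_corrected_sus, f_sus, ll_sus, ul_sus,
                     denominators.population_sus, denominators.births_sus),
    )
    supp = _sector_estimate(
        "supplementary",
        SectorInputs(hosp_corrected_supp, f_supp, ll_supp, ul_supp,
                     denominators.population_supp, denominators.births_supp),
    )
    tot_point = sus.abortions + supp.abortions
    tot_ll = sus.abortions_ll + supp.abortions_ll
    tot_ul = sus.abortions_ul + supp.abortions_ul
    total = SectorEstimate(
        name="total",
        hosp_corrected=sus.hosp_corrected + supp.hosp_corrected,
        factor=None, factor_ll=None, factor_ul=None,
        abortions=tot_point, abortions_ll=tot_ll, abortions_ul=tot_ul,
        population=denominators.population_total,
        live_births=denominators.births_total,
        rate=abortion_rate(tot_point, denominators.population_total),
        rate_ll=abortion_rate(tot_ll, denominators.population_total),
        rate_ul=abortion_rate(tot_ul, denominators.population_total),
        ratio=abortion_ratio(tot_point, denominators.births_total),
        ratio_ll=abortion_ratio(tot_ll, denominators.births_total),
        ratio_ul=abortion_ratio(tot_ul, denominators.births_total),
    )
    return EstimateResult(sus=sus, supplementary=supp, total=total)


# ---------------------------------------------------------------------------
# Run configuration and the end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and parameters of one reproducible run.

    Defaults reproduce the 2015 national analysis; only the input paths are
    mandatory.
    """

    sus_path: str
    ans_cons_path: str
    ans_det_path: str
    population_path: str
    births_path: str
    beneficiaries_paths: Sequence[str] = ()
    year: int = brazil2015.YEAR
    age_range: tuple[int, int] = (10, 49)
    ans_mode: str = "icd_or_procedure"
    exclude_in_sus: bool = False
    miscarriage_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(MiscarriageFactors().by_band)
    )
    complication_factors: Mapping[str, tuple[int, tuple[int, int]]] = field(
        default_factory=lambda: dict(brazil2015.COMPLICATION_FACTORS)
    )
    band_coverage: Mapping[str, float] = field(
        default_factory=lambda: dict(brazil2015.BAND_COVERAGE)
    )
    share_18_19: float = brazil2015.SHARE_18_19_OF_15_19
    run_scenarios: bool = True
    pna_total: float = brazil2015.PNA_TOTAL_ABORTIONS
    pna_frequency: float = brazil2015.PNA_ANNUAL_FREQUENCY
    sector_population_18_39: Mapping[str, float] = field(
        default_factory=lambda: dict(brazil2015.SECTOR_POPULATION_18_39)
    )
    rounding: str = "table"  # "table" (half-up at printed cells) or "exact"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        if "complication_factors" in raw:
            raw["complication_factors"] = {
                k: (int(v[0]), (int(v[1]), int(v[2])))
                for k, v in raw["complication_factors"].items()
            }
        return cls(**raw)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineResult:
    sus_counts: CountsTable
    ans_icd_only: CountsTable
    ans_both: CountsTable
    ans_fine: CountsTable
    n_unlinkable: int
    corrected_sus: CountsTable
    corrected_supp: CountsTable
    coverage_national_pct: float | None
    legacy_ratio_national: float | None
    hosp_sus_18_39: float | None
    hosp_supp_18_39: float | None
    scenarios: pd.DataFrame | None
    denominators: SectorDenominators
    estimate: EstimateResult
    manifest: dict

    @property
    def table6(self) -> pd.DataFrame:
        return self.estimate.to_frame()


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def full_pipeline(config: RunConfig) -> PipelineResult:
    """Run selection → corrections → calibration → estimation end to end.

    Any stage failure aborts with a :class:`PipelineStageError` naming the
    stage. The returned manifest records input digests and every parameter,
    so a run can be reproduced byte for byte.
    """
    rule = SelectionRule(mode=config.ans_mode, exclude_in_sus=config.exclude_in_sus)
    factors = MiscarriageFactors(dict(config.miscarriage_factors))

    def stage(name, fn):
        try:
            return fn()
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise PipelineStageError(name, exc) from exc

    sus_records = stage("read_sus", lambda: read_table(config.sus_path, "sus_admissions"))
    cons = stage("read_ans_cons", lambda: read_table(config.ans_cons_path, "ans_cons"))
    det = stage("read_ans_det", lambda: read_table(config.ans_det_path, "ans_det"))
    population = stage(
        "read_population",
        lambda: read_table(config.population_path, "panel", panel_kind="population"),
    )
    births = stage(
        "read_births",
        lambda: read_table(config.births_path, "panel", panel_kind="live_births"),
    )

    sus_counts = stage(
        "select_sus",
        lambda: select_sus(sus_records, rule, year=config.year,
                           age_range=config.age_range),
    )
    linkage = stage("link_ans", lambda: link_ans(cons, det, rule, year=config.year))
    ans_icd = stage("select_ans", lambda: select_ans(linkage, rule, mode="icd_only"))
    ans_both = stage(
        "select_ans", lambda: select_ans(linkage, rule, mode="icd_or_procedure")
    )
    ans_fine = stage(
        "select_ans", lambda: select_ans(linkage, rule, mode=config.ans_mode, fine=True)
    )
    ans_selected = ans_icd if config.ans_mode == "icd_only" else ans_both

    rounded = config.rounding == "table"
    corrected_sus = stage(
        "miscarriage_correction",
        lambda: apply_miscarriage(sus_counts.to_national(), factors, rounded=rounded),
    )
    corrected_supp = stage(
        "miscarriage_correction",
        lambda: apply_miscarriage(ans_selected.to_national(), factors, rounded=rounded),
    )

    coverage_pct = legacy_ratio = None
    if config.beneficiaries_paths:
        def _coverage():
            snaps = [
                read_table(p, "panel", panel_kind="beneficiaries")
                for p in config.beneficiaries_paths
            ]
            cov = compute_coverage(snaps if len(snaps) > 1 else snaps[0], population)
            est = legacy_private_estimate(
                sus_counts.to_national(), cov, rounded=rounded
            )
            ratio = estimated_reported_ratio(est, ans_selected.to_national())
            return cov.national_pct, float(ratio.loc["Total", "Total"])

        coverage_pct, legacy_ratio = stage("coverage", _coverage)

    hosp_sus = hosp_supp = None
    scenarios = None
    if config.run_scenarios:
        def _scenarios():
            h_sus, h_supp = restrict_to_survey_ages(
                sus_records, ans_fine, factors,
                share_18_19=config.share_18_19, year=config.year, rule=rule,
            )
            specs = canonical_scenarios(
                pna_total=config.pna_total,
                pop_sus=config.sector_population_18_39["sus"],
                pop_supp=config.sector_population_18_39["supplementary"],
                freq=config.pna_frequency,
            )
            return h_sus, h_supp, scenario_suite(specs, h_sus, h_supp)

        hosp_sus, hosp_supp, scenarios = stage("scenario_calibration", _scenarios)

    denominators = stage(
        "sector_denominators",
        lambda: sector_denominators(population, births, config.band_coverage),
    )
    estimate = stage(
        "estimation",
        lambda: compute_estimates(
            int(corrected_sus.total), int(corrected_supp.total),
            denominators, config.complication_factors,
        ),
    )

    manifest = {
        "inputs": {
            "sus": _sha256(config.sus_path),
            "ans_cons": _sha256(config.ans_cons_path),
            "ans_det": _sha256(config.ans_det_path),
            "population": _sha256(config.population_path),
            "births": _sha256(config.births_path),
            "beneficiaries": [_sha256(p) for p in config.beneficiaries_paths],
        },
        "parameters": {
            "year": config.year,
            "age_range": list(config.age_range),
            "ans_mode": config.ans_mode,
            "exclude_in_sus": config.exclude_in_sus,
            "miscarriage_factors": dict(config.miscarriage_factors),
            "complication_factors": {
                k: [v[0], list(v[1])] for k, v in config.complication_factors.items()
            },
            "band_coverage": dict(config.band_coverage),
            "share_18_19": config.share_18_19,
            "pna_total": config.pna_total,
            "pna_frequency": config.pna_frequency,
            "rounding": config.rounding,
        },
        "counts": {
            "sus_records": int(len(sus_records)),
            "ans_cons_rows": int(len(cons)),
            "ans_det_rows": int(len(det)),
            "unlinkable_det_events": linkage.n_unlinkable,
        },
    }

    return PipelineResult(
        sus_counts=sus_counts,
        ans_icd_only=ans_icd,
        ans_both=ans_both,
        ans_fine=ans_fine,
        n_unlinkable=linkage.n_unlinkable,
        corrected_sus=corrected_sus,
        corrected_supp=corrected_supp,
        coverage_national_pct=coverage_pct,
        legacy_ratio_national=legacy_ratio,
        hosp_sus_18_39=hosp_sus,
        hosp_supp_18_39=hosp_supp,
        scenarios=scenarios,
        denominators=denominators,
        estimate=estimate,
        manifest=manifest,
    )
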