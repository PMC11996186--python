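"""Miscarriage correction and the non-hospitalization scenario engine.

Two multiplicative corrections turn hospitalized abortion-complication
counts into induced-abortion estimates:

* a **miscarriage factor** (< 1) per maternal age band removes
  hospitalizations attributable to spontaneous abortion — prospective
  cohorts put the miscarriage share higher above age 30, hence 0.90 below
  30, 0.85 at 30–39 and 0.75 at 40–49;
* a **complications factor** (> 1) inflates hospitalized cases to all
  induced abortions, including those never reaching hospital. It is
  calibrated here against an external survey total (the ballot-box National
  Abortion Survey) by simulating scenarios that vary how the surveyed
  abortions split between the public and supplementary sectors.

The survey covers women 18–39, so calibration restricts hospitalizations to
that range: public-sector microdata carry integer ages and are filtered
directly; private-sector data only provide the 15–19 band, of which a
configurable share (75% by default) is attributed to ages 18–19.

All arithmetic that feeds a printed-style integer goes through ``Decimal``
so that exact .5 products (e.g. 7,365 × 0.90) round half-up without binary
float artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Mapping, Sequence

import pandas as pd

from . import brazil2015
from .data_io import CountsTable, coarse_band_of, round_half_up

__all__ = [
    "DEFAULT_MISCARRIAGE_FACTORS",
    "MiscarriageFactors",
    "ScenarioSpec",
    "ScenarioResult",
    "apply_miscarriage",
    "restrict_to_survey_ages",
    "run_scenario",
    "scenario_suite",
    "canonical_scenarios",
]


class ConfigurationError(ValueError):
    """A correction-factor configuration is incomplete or inconsistent."""


class UndefinedFactorError(ZeroDivisionError):
    """A factor was requested with zero hospitalizations in the denominator."""


# ---------------------------------------------------------------------------
# Miscarriage correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MiscarriageFactors:
    """Age-band multiplicative factors removing spontaneous abortions."""

    by_band: Mapping[str, float] = field(
        default_factory=lambda: {
            "10-19": 0.90, "20-29": 0.90, "30-39": 0.85, "40-49": 0.75,
        }
    )

    def __post_init__(self):
        for band, f in self.by_band.items():
            if not 0 < f <= 1:
                raise ConfigurationError(
                    f"miscarriage factor for {band} must be in (0, 1], got {f}"
                )

    def factor(self, band: str) -> Decimal:
        band = coarse_band_of(band)
        if band in self.by_band:
            return Decimal(str(self.by_band[band]))
        # merged span (e.g. "10-29"): all constituent decades must agree
        lo, hi = (int(x) for x in band.split("-"))
        decades = [f"{d}-{d + 9}" for d in range(lo, hi, 10)]
        try:
            values = {self.by_band[d] for d in decades}
        except KeyError:
            raise ConfigurationError(
                f"no miscarriage factor configured for band {band!r}"
            ) from None
        if len(values) != 1:
            raise ConfigurationError(
                f"band {band!r} pools decades with different factors"
            )
        return Decimal(str(values.pop()))


DEFAULT_MISCARRIAGE_FACTORS = MiscarriageFactors()


def _as_decimal(n: float) -> Decimal:
    return Decimal(str(int(n)) if float(n).is_integer() else repr(float(n)))


def apply_miscarriage(
    counts: CountsTable,
    factors: MiscarriageFactors = DEFAULT_MISCARRIAGE_FACTORS,
    rounded: bool = True,
) -> CountsTable:
    """Scale each cell by its band's miscarriage factor.

    Contiguous bands sharing the same factor are pooled before rounding and
    reported under a merged label (10-19 and 20-29 at 0.90 become the
    10-29 row), which is the printed-table convention — pooling matters at
    exact .5 products. With ``rounded`` (the default) each pooled cell is
    rounded half-up to an integer and totals are sums of rounded cells;
    without it the exact products are returned.
    """
    counts = counts.to_coarse()
    out: dict[tuple[str, str], float] = {}
    for region in counts.regions:
        sub = counts.cells.loc[region]
        runs: list[tuple[Decimal, list[str], Decimal]] = []
        for band in sorted(sub.index, key=lambda b: int(b.split("-")[0])):
            f = factors.factor(band)
            if runs and runs[-1][0] == f and (
                int(runs[-1][1][-1].split("-")[1]) + 1 == int(band.split("-")[0])
            ):
                runs[-1][1].append(band)
                runs[-1] = (f, runs[-1][1], runs[-1][2] + _as_decimal(sub[band]))
            else:
                runs.append((f, [band], _as_decimal(sub[band])))
        for f, bands, n in runs:
            label = f"{bands[0].split('-')[0]}-{bands[-1].split('-')[1]}"
            v = n * f
            out[(region, label)] = round_half_up(v) if rounded else float(v)
    return CountsTable.from_dict(out)


# ---------------------------------------------------------------------------
# Survey-age (18–39) restriction
# ---------------------------------------------------------------------------

def restrict_to_survey_ages(
    sus_records: pd.DataFrame,
    ans_fine_counts: CountsTable,
    factors: MiscarriageFactors = DEFAULT_MISCARRIAGE_FACTORS,
    share_18_19: float = brazil2015.SHARE_18_19_OF_15_19,
    year: int | None = None,
    rule: "SelectionRule | None" = None,
) -> tuple[float, float]:
    """Miscarriage-corrected abortion hospitalizations of women 18–39.

    Public sector: qualifying abortion records (per ``rule``) with integer
    age 18–39 are counted directly. Private sector: the 18–19 contribution
    is ``share_18_19`` × the 15–19 fine-band count, added to the 20–39
    bands. Each sector total is rounded half-up once, at the total (the
    convention of the published calibration table).
    """
    from .case_selection import DEFAULT_RULE, sus_abortion_mask

    if not 0 <= share_18_19 <= 1:
        raise ConfigurationError(f"share_18_19 must be in [0, 1], got {share_18_19}")
    rule = rule or DEFAULT_RULE
    rec = sus_records.loc[
        sus_abortion_mask(sus_records, rule, year=year, age_range=(18, 39))
    ]
    n_18_29 = int(rec["age"].between(18, 29).sum())
    n_30_39 = int(rec["age"].between(30, 39).sum())
    f_u30 = factors.factor("20-29")
    f_30s = factors.factor("30-39")
    sus = Decimal(n_18_29) * f_u30 + Decimal(n_30_39) * f_30s

    if ans_fine_counts.granularity != "fine":
        raise ConfigurationError(
            "private-sector counts must be on 5-year bands to attribute the "
            "18-19 contribution; supply fine-band input"
        )
    bt = ans_fine_counts.band_totals()
    c = lambda b: Decimal(repr(float(bt.get(b, 0.0))))
    supp_u30 = Decimal(str(share_18_19)) * c("15-19") + c("20-24") + c("25-29")
    supp_30s = c("30-34") + c("35-39")
    supp = supp_u30 * f_u30 + supp_30s * f_30s
    return round_half_up(sus), round_half_up(supp)


# ---------------------------------------------------------------------------
# Scenario engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one calibration scenario.

    Three modes, resolved in this order:

    * ``pooled`` — one factor for all women: survey total ÷ total
      hospitalizations;
    * *constrained* (``freq_ratio`` set) — sector frequencies in a fixed
      ratio k = freq_supp/freq_sus, with freq_sus solved so the sector
      estimates sum to the survey total;
    * *sector* — explicit annual abortion frequencies per sector
      (``freq_supp`` defaults to ``freq_sus``).

    Sector populations are the women 18–39 attributable to each funding
    sector; they are explicit inputs, not derived quantities.
    """

    name: str = "scenario"
    pooled: bool = False
    pna_total: float | None = None
    pop_sus: float | None = None
    pop_supp: float | None = None
    freq_sus: float | None = None
    freq_supp: float | None = None
    freq_ratio: float | None = None

    def __post_init__(self):
        for f in (self.freq_sus, self.freq_supp):
            if f is not None and not 0 < f < 1:
                raise ConfigurationError(f"abortion frequency must be in (0,1), got {f}")
        for p in (self.pop_sus, self.pop_supp):
            if p is not None and p <= 0:
                raise ConfigurationError("sector populations must be positive")

    @property
    def mode(self) -> str:
        if self.pooled:
            return "pooled"
        if self.freq_ratio is not None:
            return "constrained"
        return "sector"


@dataclass(frozen=True)
class ScenarioResult:
    """Derived correction factors for one scenario.

    Estimated sector abortions are integers; factors are reported to one
    decimal, each being estimated abortions ÷ the corresponding
    miscarriage-corrected hospitalizations.
    """

    name: str
    mode: str
    est_abortions_sus: float | None
    est_abortions_supp: float | None
    hosp_sus_18_39: float
    hosp_supp_18_39: float
    factor_sus: float | None
    factor_supp: float | None
    factor_total: float | None
    freq_sus: float | None = None
    freq_supp: float | None = None


def _factor(numer: float, hosp: float, what: str) -> float:
    if hosp <= 0:
        raise UndefinedFactorError(
            f"cannot form the {what} factor: zero hospitalizations"
        )
    return round_half_up(numer / hosp, 1)


def run_scenario(
    spec: ScenarioSpec, hosp_sus_18_39: float, hosp_supp_18_39: float
) -> ScenarioResult:
    """Derive correction factors for one scenario.

    ``hosp_*_18_39`` are the miscarriage-corrected hospitalizations of women
    18–39 from :func:`restrict_to_survey_ages`.
    """
    if spec.mode == "pooled":
        if spec.pna_total is None:
            raise ConfigurationError("pooled scenario requires pna_total")
        total_hosp = hosp_sus_18_39 + hosp_supp_18_39
        return ScenarioResult(
            name=spec.name, mode="pooled",
            est_abortions_sus=None, est_abortions_supp=None,
            hosp_sus_18_39=hosp_sus_18_39, hosp_supp_18_39=hosp_supp_18_39,
            factor_sus=None, factor_supp=None,
            factor_total=_factor(spec.pna_total, total_hosp, "pooled"),
        )

    if spec.pop_sus is None or spec.pop_supp is None:
        raise ConfigurationError(f"{spec.mode} scenario requires sector populations")

    if spec.mode == "constrained":
        if spec.pna_total is None:
            raise ConfigurationError("constrained scenario requires pna_total")
        k = spec.freq_ratio
        if k is None or k < 0:
            raise ConfigurationError("freq_ratio must be non-negative")
        # one unknown: pop_sus*f + pop_supp*(k*f) = pna_total
        freq_sus = spec.pna_total / (spec.pop_sus + k * spec.pop_supp)
        freq_supp = k * freq_sus
    else:
        if spec.freq_sus is None:
            raise ConfigurationError("sector scenario requires freq_sus")
        freq_sus = spec.freq_sus
        freq_supp = spec.freq_supp if spec.freq_supp is not None else freq_sus

    est_sus = round_half_up(spec.pop_sus * freq_sus)
    est_supp = round_half_up(spec.pop_supp * freq_supp)
    return ScenarioResult(
        name=spec.name, mode=spec.mode,
        est_abortions_sus=est_sus, est_abortions_supp=est_supp,
        hosp_sus_18_39=hosp_sus_18_39, hosp_supp_18_39=hosp_supp_18_39,
        factor_sus=_factor(est_sus, hosp_sus_18_39, "public-sector"),
        factor_supp=_factor(est_supp, hosp_supp_18_39, "supplementary"),
        factor_total=None,
        freq_sus=freq_sus, freq_supp=freq_supp,
    )


def canonical_scenarios(
    pna_total: float = brazil2015.PNA_TOTAL_ABORTIONS,
    pop_sus: float = brazil2015.SECTOR_POPULATION_18_39["sus"],
    pop_supp: float = brazil2015.SECTOR_POPULATION_18_39["supplementary"],
    freq: float = brazil2015.PNA_ANNUAL_FREQUENCY,
) -> list[ScenarioSpec]:
    """The five published calibration scenarios.

    1 pools all women; 2 assumes the survey frequency in both sectors;
    3a/3b/3c assume the supplementary-sector frequency is 50%, 75% and 90%
    of the public-sector one, solved to match the survey total.
    """
    common = dict(pop_sus=pop_sus, pop_supp=pop_supp)
    return [
        ScenarioSpec(name="1", pooled=True, pna_total=pna_total),
        ScenarioSpec(name="2", freq_sus=freq, freq_supp=freq, **common),
        ScenarioSpec(name="3a", freq_ratio=0.50, pna_total=pna_total, **common),
        ScenarioSpec(name="3b", freq_ratio=0.75, pna_total=pna_total, **common),
        ScenarioSpec(name="3c", freq_ratio=0.90, pna_total=pna_total, **common),
    ]


def scenario_suite(
    specs: Sequence[ScenarioSpec],
    hosp_sus_18_39: float,
    hosp_supp_18_39: float,
) -> pd.DataFrame:
    """Run each scenario and tabulate the results.

    Columns follow the published layout: survey total (a), estimated sector
    abortions (b, c), corrected hospitalizations (d, e, f) and the three
    factors (b/d, c/e, a/f).
    """
    rows = []
    for spec in specs:
        res = run_scenario(spec, hosp_sus_18_39, hosp_supp_18_39)
        rows.append(
            {
                "scenario": res.name,
                "pna_total": spec.pna_total,
                "est_abortions_sus": res.est_abortions_sus,
                "est_abortions_supp": res.est_abortions_supp,
                "hosp_sus_18_39": res.hosp_sus_18_39,
                "hosp_supp_18_39": res.hosp_supp_18_39,
                "hosp_total_18_39": res.hosp_sus_18_39 + res.hosp_supp_18_39,
                "factor_sus": res.factor_sus,
                "factor_supp": res.factor_supp,
                "factor_total": res.factor_total,
            }
        )
    return pd.DataFrame(rows)
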