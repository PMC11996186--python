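"""Select abortion hospitalizations in public and private claims data.

Public-sector (SIH/SUS-like) records are selected when any of the five
diagnosis fields carries an abortion-outcome ICD-10 category (O03–O08 by
default); ectopic/molar/abnormal-conception categories (O00–O02) are never
counted as abortion outcomes. Private-sector (ANS-like) data come in two
linked tables — consolidated events with up to four ICD fields (possibly
withheld) and per-procedure detail rows — joined on the care-event id so a
woman with both an ICD and a procedure is counted once. Because insurers may
withhold the ICD, the private-sector case definition can optionally include
events identified only by a post-abortion procedure (manual vacuum
aspiration or curettage).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    COARSE_BANDS,
    CountsTable,
    band_of_age,
    coarse_band_of,
    icd_category_series,
)

__all__ = [
    "DEFAULT_RULE",
    "SelectionRule",
    "AnsEvent",
    "AnsLinkage",
    "sus_abortion_mask",
    "select_sus",
    "link_ans",
    "select_ans",
    "icd_procedure_ratio",
]

_INCLUDE_DEFAULT = frozenset({"O03", "O04", "O05", "O06", "O07", "O08"})
_EXCLUDE_DEFAULT = frozenset({"O00", "O01", "O02"})
_PROCEDURES_DEFAULT = frozenset({"31309020", "31303013", "31309062"})


@dataclass(frozen=True)
class SelectionRule:
    """ICD categories and procedure codes defining an abortion case.

    ``mode`` selects the private-sector definition: ``icd_only`` or
    ``icd_or_procedure``. ``exclude_in_sus`` optionally applies the O00–O02
    exclusion symmetrically to public-sector records (the published
    procedure states the exclusion only for the private selection, so the
    default is False).
    """

    include_categories: frozenset[str] = _INCLUDE_DEFAULT
    exclude_categories: frozenset[str] = _EXCLUDE_DEFAULT
    procedure_codes: frozenset[str] = _PROCEDURES_DEFAULT
    mode: str = "icd_or_procedure"
    exclude_in_sus: bool = False

    def __post_init__(self):
        if self.include_categories & self.exclude_categories:
            raise ValueError("include and exclude ICD category sets overlap")
        if self.mode not in ("icd_only", "icd_or_procedure"):
            raise ValueError(f"unknown selection mode {self.mode!r}")

    def with_mode(self, mode: str) -> "SelectionRule":
        return replace(self, mode=mode)


DEFAULT_RULE = SelectionRule()


# ---------------------------------------------------------------------------
# Public sector
# ---------------------------------------------------------------------------

def sus_abortion_mask(
    records: pd.DataFrame,
    rule: SelectionRule = DEFAULT_RULE,
    year: int | None = None,
    age_range: tuple[int, int] = (10, 49),
) -> pd.Series:
    """Boolean mask of records qualifying as abortion hospitalizations.

    A record qualifies iff its year matches (when ``year`` is given), the
    woman's age lies within ``age_range``, and at least one diagnosis field
    carries an included ICD category (optionally none an excluded one, when
    ``rule.exclude_in_sus`` is set).
    """
    lo, hi = age_range
    mask = records["age"].between(lo, hi)
    if year is not None:
        mask &= records["year"] == year

    diag_cols = [c for c in records.columns if c.startswith("diag")]
    has_included = pd.Series(False, index=records.index)
    has_excluded = pd.Series(False, index=records.index)
    for c in diag_cols:
        cats = icd_category_series(records[c])
        has_included |= cats.isin(rule.include_categories)
        has_excluded |= cats.isin(rule.exclude_categories)
    mask &= has_included
    if rule.exclude_in_sus:
        mask &= ~has_excluded
    return mask


def select_sus(
    records: pd.DataFrame,
    rule: SelectionRule = DEFAULT_RULE,
    year: int | None = None,
    age_range: tuple[int, int] = (10, 49),
) -> CountsTable:
    """Count qualifying public-sector hospitalizations by region × decade band.

    Selection follows :func:`sus_abortion_mask`. The unit is the
    hospitalization: readmissions of the same woman count separately, as in
    the source data.
    """
    sel = records.loc[sus_abortion_mask(records, rule, year, age_range)]
    if sel.empty:
        return CountsTable.zeros(sorted(records["region"].unique()) or ["BR"],
                                 COARSE_BANDS)
    bands = sel["age"].map(lambda a: band_of_age(int(a)))
    counts = sel.groupby([sel["region"], bands.rename("age_band")]).size()
    table = CountsTable(counts.astype(float))
    # complete the grid with explicit zero cells
    full = CountsTable.zeros(table.regions, COARSE_BANDS)
    return table + full


# ---------------------------------------------------------------------------
# Private sector: linkage and selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnsEvent:
    """One private-sector care event after CONS/DET linkage."""

    event_id: str
    region: str | None
    age_band: str | None
    has_abortion_icd: bool
    has_excluded_icd: bool
    has_abortion_procedure: bool


@dataclass
class AnsLinkage:
    """Deduplicated events plus linkage diagnostics.

    ``events`` has one row per distinct event id with columns
    ``event_id, region, age_band, has_abortion_icd, has_excluded_icd,
    has_abortion_procedure``. Detail rows whose event id never appears in
    the consolidated table have no known region or band; they are retained
    here (region/band null) and counted in ``n_unlinkable`` but excluded
    from stratified tables.
    """

    events: pd.DataFrame
    n_unlinkable: int = 0

    def to_records(self) -> list[AnsEvent]:
        return [
            AnsEvent(
                event_id=r.event_id,
                region=None if pd.isna(r.region) else r.region,
                age_band=None if pd.isna(r.age_band) else r.age_band,
                has_abortion_icd=bool(r.has_abortion_icd),
                has_excluded_icd=bool(r.has_excluded_icd),
                has_abortion_procedure=bool(r.has_abortion_procedure),
            )
            for r in self.events.itertuples(index=False)
        ]


def link_ans(
    cons: pd.DataFrame,
    det: pd.DataFrame,
    rule: SelectionRule = DEFAULT_RULE,
    year: int | None = None,
    age_bands: Sequence[str] | None = None,
) -> AnsLinkage:
    """Join consolidated and detail tables into one event per care-event id.

    Flags are computed over *all* ICD fields of all consolidated rows and
    all procedure rows of the event, so duplicated detail rows never change
    the outcome.
    """
    cons = cons.copy()
    if year is not None:
        cons = cons[cons["year"] == year]
    if age_bands is not None:
        cons = cons[cons["age_band"].isin(age_bands)]

    icd_cols = [c for c in cons.columns if c.startswith("icd")]
    has_inc = pd.Series(False, index=cons.index)
    has_exc = pd.Series(False, index=cons.index)
    for c in icd_cols:
        cats = icd_category_series(cons[c])
        has_inc |= cats.isin(rule.include_categories)
        has_exc |= cats.isin(rule.exclude_categories)

    by_event = (
        pd.DataFrame(
            {
                "event_id": cons["event_id"],
                "region": cons["region"],
                "age_band": cons["age_band"],
                "has_abortion_icd": has_inc,
                "has_excluded_icd": has_exc,
            }
        )
        .groupby("event_id", as_index=False)
        .agg(
            region=("region", "first"),
            age_band=("age_band", "first"),
            has_abortion_icd=("has_abortion_icd", "any"),
            has_excluded_icd=("has_excluded_icd", "any"),
        )
    )

    proc = (
        det.assign(
            hit=det["procedure_code"].astype(str).str.strip().isin(rule.procedure_codes)
        )
        .groupby("event_id", as_index=False)["hit"]
        .any()
        .rename(columns={"hit": "has_abortion_procedure"})
    )

    events = by_event.merge(proc, on="event_id", how="outer")
    for col in ("has_abortion_icd", "has_excluded_icd", "has_abortion_procedure"):
        events[col] = events[col].astype("boolean").fillna(False).astype(bool)
    n_unlinkable = int(events["region"].isna().sum())
    return AnsLinkage(events=events, n_unlinkable=n_unlinkable)


def select_ans(
    linkage: AnsLinkage,
    rule: SelectionRule = DEFAULT_RULE,
    mode: str | None = None,
    fine: bool = False,
) -> CountsTable:
    """Count qualifying private-sector events by region × age band.

    ``icd_only`` counts events with an abortion ICD; ``icd_or_procedure``
    additionally counts events identified only by a qualifying procedure.
    Events carrying any excluded (O00–O02) category are never counted.
    Events without a known stratum (detail-only) are excluded here; they are
    reported in ``linkage.n_unlinkable``.
    """
    mode = mode or rule.mode
    if mode not in ("icd_only", "icd_or_procedure"):
        raise ValueError(f"unknown selection mode {mode!r}")
    ev = linkage.events
    eligible = ~ev["has_excluded_icd"] & ev["region"].notna()
    if mode == "icd_only":
        eligible &= ev["has_abortion_icd"]
    else:
        eligible &= ev["has_abortion_icd"] | ev["has_abortion_procedure"]
    sel = ev.loc[eligible]

    regions = sorted(ev["region"].dropna().unique()) or ["BR"]
    if sel.empty:
        zero = CountsTable.zeros(regions, COARSE_BANDS)
        return zero  # coarse zero table; fine zero would have no information
    counts = sel.groupby(["region", "age_band"]).size()
    table = CountsTable(counts.astype(float))
    if fine:
        return table
    table = table.to_coarse()
    return table + CountsTable.zeros(regions, COARSE_BANDS)


def icd_procedure_ratio(
    table_both: CountsTable, table_icd: CountsTable, ndigits: int = 1
) -> pd.DataFrame:
    """Cell-wise ratio of the ICD-or-procedure to the ICD-only counts.

    Quantifies how much the procedure route adds on top of the (under-)
    reported ICDs. Cells with a zero ICD-only denominator are undefined
    (NaN). Marginal ratios come from marginal totals.
    """
    return table_both.ratio_to(table_icd, ndigits=ndigits)
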