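"""Domain types, age bands, ICD helpers and tabular I/O.

The pipeline works on five tabular inputs, all plain UTF-8 CSV with header:

* ``sus_admissions`` — public-sector (SIH/SUS-like) hospitalization records,
  one row per admission, with the woman's integer age and up to five ICD-10
  diagnosis fields (principal, secondary, death, associated, notification).
* ``ans_cons`` — private-sector (ANS-like) consolidated care events with a
  5-year age band and up to four ICD-10 fields, any of which may be withheld.
* ``ans_det`` — per-procedure detail rows linkable to ``ans_cons`` by event id.
* ``panel`` — population / insurance-beneficiary / live-birth counts by
  region and age band.
* ``counts`` — the universal aggregate: counts by region × age band.

A thin schema registry maps source-specific column names onto these canonical
schemas, so real administrative exports can be adapted by configuration alone.
Region codes are opaque strings (2-letter federative-unit codes by default);
nothing hard-codes a particular set of regions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FINE_BANDS",
    "COARSE_BANDS",
    "MISSING_ICD_TOKEN",
    "SchemaError",
    "RecordValidationError",
    "InvalidCodeError",
    "SusAdmissionRecord",
    "AnsConsRecord",
    "AnsDetRecord",
    "CountsTable",
    "PanelTable",
    "band_of_age",
    "coarse_band_of",
    "icd_category",
    "is_valid_icd",
    "read_table",
    "write_table",
    "round_half_up",
]

# ---------------------------------------------------------------------------
# Age bands
# ---------------------------------------------------------------------------

FINE_BANDS: tuple[str, ...] = (
    "10-14", "15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
)
COARSE_BANDS: tuple[str, ...] = ("10-19", "20-29", "30-39", "40-49")

#: merged decade spans, as printed in tables that pool bands sharing a
#: correction factor (e.g. the 10-29 row).
MERGED_BANDS: tuple[str, ...] = (
    "10-29", "20-39", "30-49", "10-39", "20-49", "10-49",
)

_ALL_BANDS = set(FINE_BANDS) | set(COARSE_BANDS) | set(MERGED_BANDS)


def band_of_age(age: int, *, fine: bool = False) -> str:
    """Map an integer age in [10, 49] to its 10-year (or 5-year) band."""
    if not 10 <= age <= 49:
        raise ValueError(f"age {age} outside the reproductive range 10-49")
    if fine:
        lo = (age // 5) * 5
        return f"{lo}-{lo + 4}"
    lo = (age // 10) * 10
    return f"{lo}-{lo + 9}"


def coarse_band_of(band: str) -> str:
    """Aggregate a fine (5-year) band label onto its decade band."""
    if band in COARSE_BANDS or band in MERGED_BANDS:
        return band
    if band not in FINE_BANDS:
        raise ValueError(f"unknown age band {band!r}")
    lo = (int(band[:2]) // 10) * 10
    return f"{lo}-{lo + 9}"


def band_sort_key(band: str) -> tuple[int, int]:
    return (int(band.split("-")[0]), int(band.split("-")[1]))


def _granularity(bands: Iterable[str]) -> str:
    bands = set(bands)
    if bands <= set(COARSE_BANDS) | set(MERGED_BANDS):
        return "coarse"
    if bands <= set(FINE_BANDS):
        return "fine"
    unknown = bands - _ALL_BANDS
    if unknown:
        raise ValueError(f"unknown age band labels: {sorted(unknown)}")
    raise ValueError("mixed fine and coarse age bands in one table")


# ---------------------------------------------------------------------------
# Rounding
# ---------------------------------------------------------------------------

def round_half_up(x: float | Decimal, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables).

    Exact .5 ties produced by decimal factors (e.g. 7,365 × 0.90 = 6,628.5)
    must round up; callers that need exactness pass a ``Decimal``.
    """
    d = x if isinstance(x, Decimal) else Decimal(repr(float(x)))
    q = d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)
    return float(q)


# ---------------------------------------------------------------------------
# ICD-10 codes
# ---------------------------------------------------------------------------

#: token used in CSV files for an ICD field the insurer withheld (distinct
#: from an empty field, which means "no code recorded in this slot").
MISSING_ICD_TOKEN = "NA"

_ICD_RE = re.compile(r"[A-Za-z][0-9]{2}\.?[0-9]{0,2}")


class InvalidCodeError(ValueError):
    """An ICD-10 code string too short or malformed to classify."""


def is_valid_icd(code: str) -> bool:
    return bool(_ICD_RE.fullmatch(code.strip()))


def icd_category(code: str) -> str:
    """Return the 3-character ICD-10 category: ``"O034" -> "O03"``.

    Selection rules operate on categories, so subcoded diagnoses
    (O03.4, O062) match their parent category.
    """
    code = code.strip().upper()
    if len(code) < 3 or not _ICD_RE.fullmatch(code):
        raise InvalidCodeError(f"not an ICD-10 code: {code!r}")
    return code[:3]


def icd_category_series(s: pd.Series) -> pd.Series:
    """Vectorised :func:`icd_category`; missing/empty entries become NaN."""
    out = s.astype("string").str.strip().str.upper().str[:3]
    return out.where(out.str.len() == 3)


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """CSV header does not match the declared schema."""


class RecordValidationError(ValueError):
    """One or more rows failed validation; ``errors`` lists (row, message)."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        preview = "; ".join(f"row {r}: {m}" for r, m in errors[:5])
        more = "" if len(errors) <= 5 else f" (+{len(errors) - 5} more)"
        super().__init__(f"{len(errors)} invalid record(s): {preview}{more}")


@dataclass(frozen=True)
class SusAdmissionRecord:
    """One public-sector hospitalization (AIH-like record).

    ``diagnoses`` holds up to five ICD-10 code strings in the order
    principal, secondary, death, associated, notification; empty strings
    mark unused slots.
    """

    region: str
    age: int
    diagnoses: tuple[str, str, str, str, str]
    year: int

    def validate(self) -> None:
        if not 0 <= self.age <= 120:
            raise ValueError(f"age {self.age} outside 0-120")
        for code in self.diagnoses:
            if code and not is_valid_icd(code):
                raise ValueError(f"malformed ICD-10 code {code!r}")


@dataclass(frozen=True)
class AnsConsRecord:
    """One consolidated private-sector care event.

    ``diagnoses`` holds four slots; ``None`` means the insurer withheld the
    ICD (legally permitted), which is distinct from ``""`` (unused slot).
    """

    event_id: str
    region: str
    age_band: str
    diagnoses: tuple[str | None, str | None, str | None, str | None]
    year: int

    def validate(self) -> None:
        if not self.event_id:
            raise ValueError("empty event_id")
        if self.age_band not in FINE_BANDS:
            raise ValueError(f"age_band {self.age_band!r} is not a 5-year band")
        for code in self.diagnoses:
            if code and not is_valid_icd(code):
                raise ValueError(f"malformed ICD-10 code {code!r}")


@dataclass(frozen=True)
class AnsDetRecord:
    """One procedure detail row, linkable to a consolidated event."""

    event_id: str
    procedure_code: str

    def validate(self) -> None:
        if not self.event_id:
            raise ValueError("empty event_id")
        if not self.procedure_code.strip():
            raise ValueError("empty procedure_code")


# ---------------------------------------------------------------------------
# Aggregate tables
# ---------------------------------------------------------------------------

class CountsTable:
    """Counts indexed by (region, age_band) — the universal aggregate.

    Wraps a :class:`pandas.Series` with a two-level index; provides margins,
    fine→coarse aggregation and table-shaped output. Values may be floats
    when an operation (e.g. an unrounded correction) produces them.
    """

    def __init__(self, cells: pd.Series):
        if not isinstance(cells.index, pd.MultiIndex) or cells.index.nlevels != 2:
            raise ValueError("cells must be indexed by (region, age_band)")
        cells = cells.copy()
        cells.index = cells.index.set_names(["region", "age_band"])
        if (cells < 0).any():
            bad = cells[cells < 0].index[0]
            raise ValueError(f"negative count at {bad}")
        self._granularity = _granularity(cells.index.get_level_values("age_band"))
        order = sorted(
            cells.index,
            key=lambda k: (str(k[0]), band_sort_key(k[1])),
        )
        self.cells = cells.loc[order]

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping[tuple[str, str], float]) -> "CountsTable":
        idx = pd.MultiIndex.from_tuples(list(d), names=["region", "age_band"])
        return cls(pd.Series(list(d.values()), index=idx))

    @classmethod
    def from_band_totals(
        cls, totals: Mapping[str, float], region: str = "BR"
    ) -> "CountsTable":
        return cls.from_dict({(region, b): v for b, v in totals.items()})

    @classmethod
    def zeros(cls, regions: Sequence[str], bands: Sequence[str]) -> "CountsTable":
        return cls.from_dict({(r, b): 0 for r in regions for b in bands})

    # -- basic properties --------------------------------------------------

    @property
    def granularity(self) -> str:
        return self._granularity

    @property
    def bands(self) -> list[str]:
        return sorted(
            set(self.cells.index.get_level_values("age_band")), key=band_sort_key
        )

    @property
    def regions(self) -> list[str]:
        return sorted(set(self.cells.index.get_level_values("region")))

    @property
    def total(self) -> float:
        return float(self.cells.sum())

    def band_totals(self) -> pd.Series:
        s = self.cells.groupby(level="age_band").sum()
        return s.loc[sorted(s.index, key=band_sort_key)]

    def region_totals(self) -> pd.Series:
        return self.cells.groupby(level="region").sum().sort_index()

    # -- transforms --------------------------------------------------------

    def to_coarse(self) -> "CountsTable":
        """Aggregate 5-year bands onto decade bands (totals preserved)."""
        if self._granularity == "coarse":
            return CountsTable(self.cells)
        idx = self.cells.index
        coarse = [coarse_band_of(b) for b in idx.get_level_values("age_band")]
        s = self.cells.groupby(
            [idx.get_level_values("region"), pd.Index(coarse, name="age_band")]
        ).sum()
        return CountsTable(s)

    def to_national(self, label: str = "BR") -> "CountsTable":
        """Collapse all regions into a single national row."""
        return CountsTable.from_band_totals(self.band_totals().to_dict(), label)

    def reindex_union(self, other: "CountsTable") -> tuple[pd.Series, pd.Series]:
        a, b = self.cells.align(other.cells, fill_value=0)
        return a, b

    def scale(self, c: float) -> "CountsTable":
        return CountsTable(self.cells * c)

    def __add__(self, other: "CountsTable") -> "CountsTable":
        a, b = self.reindex_union(other)
        return CountsTable(a + b)

    def __eq__(self, other: object) -> bool:  # cell-for-cell equality
        if not isinstance(other, CountsTable):
            return NotImplemented
        a, b = self.reindex_union(other)
        return bool((a == b).all())

    def __repr__(self) -> str:
        return (
            f"<{type(self).__name__} {len(self.regions)} region(s) × "
            f"{len(self.bands)} band(s), total={self.total:,.0f}>"
        )

    # -- ratios ------------------------------------------------------------

    def ratio_to(self, denominator: "CountsTable", ndigits: int = 1) -> pd.DataFrame:
        """Cell-wise ``self / denominator`` as a wide table with margins.

        Cells with a zero denominator are undefined (NaN — printed tables
        show "-"); they are data, not errors. Marginal ratios are computed
        from marginal totals, not by averaging cell ratios.
        """
        num, den = self.reindex_union(denominator)
        wide_n = num.unstack("age_band")
        wide_d = den.unstack("age_band")
        for w in (wide_n, wide_d):
            w.loc["Total"] = w.sum()
            w["Total"] = w.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = wide_n / wide_d
        ratio[wide_d == 0] = np.nan
        return ratio.map(lambda v: round_half_up(v, ndigits) if pd.notna(v) else v)

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: one row per region, one column per band, plus margins."""
        wide = self.cells.unstack("age_band")
        wide = wide[sorted(wide.columns, key=band_sort_key)]
        wide["Total"] = wide.sum(axis=1)
        wide.loc["Total"] = wide.sum()
        return wide

    def write_csv(self, path: str | Path) -> None:
        df = self.cells.rename("count").reset_index()
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "CountsTable":
        return read_table(path, "counts")


class PanelTable(CountsTable):
    """A population-scale panel (population, beneficiaries or live births)."""

    KINDS = ("population", "beneficiaries", "live_births")

    def __init__(self, cells: pd.Series, kind: str = "population"):
        if kind not in self.KINDS:
            raise ValueError(f"unknown panel kind {kind!r}")
        super().__init__(cells)
        self.kind = kind

    @classmethod
    def from_band_totals(
        cls, totals: Mapping[str, float], region: str = "BR", kind: str = "population"
    ) -> "PanelTable":
        idx = pd.MultiIndex.from_tuples(
            [(region, b) for b in totals], names=["region", "age_band"]
        )
        return cls(pd.Series(list(totals.values()), index=idx), kind=kind)


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

SCHEMAS: dict[str, list[str]] = {
    "sus_admissions": ["region", "age", "diag1", "diag2", "diag3", "diag4", "diag5", "year"],
    "ans_cons": ["event_id", "region", "age_band", "icd1", "icd2", "icd3", "icd4", "year"],
    "ans_det": ["event_id", "procedure_code"],
    "panel": ["region", "age_band", "count"],
    "counts": ["region", "age_band", "count"],
}

_SUS_DIAGS = ["diag1", "diag2", "diag3", "diag4", "diag5"]
_ANS_ICDS = ["icd1", "icd2", "icd3", "icd4"]


def _read_csv(path: str | Path, kind: str, column_map: Mapping[str, str] | None):
    want = SCHEMAS[kind]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in want if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: schema {kind!r} missing column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    return df[want]


def read_table(
    path: str | Path,
    schema_kind: str,
    *,
    column_map: Mapping[str, str] | None = None,
    panel_kind: str = "population",
):
    """Read and validate one of the five canonical CSV inputs.

    Returns a typed :class:`pandas.DataFrame` for record-level kinds
    (``sus_admissions``, ``ans_cons``, ``ans_det``) and a
    :class:`PanelTable` / :class:`CountsTable` for aggregate kinds.
    Any unparseable row aborts the read with a
    :class:`RecordValidationError` naming the offending rows.
    """
    if schema_kind not in SCHEMAS:
        raise ValueError(f"unknown schema kind {schema_kind!r}")
    df = _read_csv(path, schema_kind, column_map)
    errors: list[tuple[int, str]] = []

    if schema_kind == "sus_admissions":
        age = pd.to_numeric(df["age"], errors="coerce")
        for i in df.index[age.isna()]:
            errors.append((int(i) + 2, f"unparseable age {df.at[i, 'age']!r}"))
        year = pd.to_numeric(df["year"], errors="coerce")
        for i in df.index[year.isna()]:
            errors.append((int(i) + 2, f"unparseable year {df.at[i, 'year']!r}"))
        for col in _SUS_DIAGS:
            bad = df[col].map(lambda c: bool(c) and not is_valid_icd(c))
            for i in df.index[bad]:
                errors.append((int(i) + 2, f"malformed ICD in {col}: {df.at[i, col]!r}"))
        if errors:
            raise RecordValidationError(errors)
        out = df.copy()
        out["age"] = age.astype(int)
        out["year"] = year.astype(int)
        bad_age = ~out["age"].between(0, 120)
        if bad_age.any():
            raise RecordValidationError(
                [(int(i) + 2, f"age {out.at[i, 'age']} outside 0-120")
                 for i in out.index[bad_age]]
            )
        return out

    if schema_kind == "ans_cons":
        year = pd.to_numeric(df["year"], errors="coerce")
        for i in df.index[year.isna()]:
            errors.append((int(i) + 2, f"unparseable year {df.at[i, 'year']!r}"))
        bad_band = ~df["age_band"].isin(FINE_BANDS)
        for i in df.index[bad_band]:
            errors.append((int(i) + 2, f"age_band {df.at[i, 'age_band']!r} is not a 5-year band"))
        for i in df.index[df["event_id"].str.strip() == ""]:
            errors.append((int(i) + 2, "empty event_id"))
        for col in _ANS_ICDS:
            bad = df[col].map(
                lambda c: bool(c) and c != MISSING_ICD_TOKEN and not is_valid_icd(c)
            )
            for i in df.index[bad]:
                errors.append((int(i) + 2, f"malformed ICD in {col}: {df.at[i, col]!r}"))
        if errors:
            raise RecordValidationError(errors)
        out = df.copy()
        out["year"] = year.astype(int)
        # explicit null token -> missing; "" stays "" (unused slot)
        for col in _ANS_ICDS:
            out[col] = out[col].replace(MISSING_ICD_TOKEN, None)
        return out

    if schema_kind == "ans_det":
        for i in df.index[df["event_id"].str.strip() == ""]:
            errors.append((int(i) + 2, "empty event_id"))
        for i in df.index[df["procedure_code"].str.strip() == ""]:
            errors.append((int(i) + 2, "empty procedure_code"))
        if errors:
            raise RecordValidationError(errors)
        return df.copy()

    # aggregate kinds
    count = pd.to_numeric(df["count"], errors="coerce")
    for i in df.index[count.isna()]:
        errors.append((int(i) + 2, f"unparseable count {df.at[i, 'count']!r}"))
    if errors:
        raise RecordValidationError(errors)
    idx = pd.MultiIndex.from_arrays(
        [df["region"], df["age_band"]], names=["region", "age_band"]
    )
    cells = pd.Series(count.to_numpy(), index=idx)
    if schema_kind == "panel":
        return PanelTable(cells, kind=panel_kind)
    return CountsTable(cells)


def write_table(obj, path: str | Path, schema_kind: str | None = None) -> None:
    """Write a table or record frame back to its canonical CSV layout."""
    if isinstance(obj, CountsTable):
        obj.write_csv(path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


# -- record <-> frame helpers (small-data convenience, used in tests) -------

def frame_from_records(records: Sequence, kind: str) -> pd.DataFrame:
    rows = []
    for r in records:
        r.validate()
        if kind == "sus_admissions":
            rows.append([r.region, r.age, *r.diagnoses, r.year])
        elif kind == "ans_cons":
            diags = [MISSING_ICD_TOKEN if d is None else d for d in r.diagnoses]
            rows.append([r.event_id, r.region, r.age_band, *diags, r.year])
        elif kind == "ans_det":
            rows.append([r.event_id, r.procedure_code])
        else:
            raise ValueError(f"unknown record kind {kind!r}")
    df = pd.DataFrame(rows, columns=SCHEMAS[kind])
    if kind == "ans_cons":
        for col in _ANS_ICDS:
            df[col] = df[col].replace(MISSING_ICD_TOKEN, None)
    return df
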