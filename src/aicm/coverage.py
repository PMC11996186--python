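"""Health-insurance coverage and the legacy coverage-factor estimator.

Earlier national studies had no private-sector hospitalization data and
estimated it as public-sector counts × insurance coverage. With reported
private claims now available, that legacy estimator can be evaluated: this
module computes coverage by region × age band from beneficiary and
population panels, applies the legacy estimator, and forms the
estimated/reported ratio that quantifies its bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import CountsTable, PanelTable, round_half_up

__all__ = [
    "CoverageTable",
    "compute_coverage",
    "legacy_private_estimate",
    "estimated_reported_ratio",
]


@dataclass
class CoverageTable:
    """Insurance-coverage proportions by (region, age band).

    ``national_by_band`` and ``national`` are computed from summed
    numerators and denominators — never by averaging percentages.
    """

    cells: pd.Series
    national_by_band: pd.Series
    national: float

    def __post_init__(self):
        if ((self.cells < 0) | (self.cells > 1)).any():
            bad = self.cells[(self.cells < 0) | (self.cells > 1)].index[0]
            raise ValueError(f"coverage outside [0, 1] at {bad}")

    @property
    def national_pct(self) -> float:
        return round_half_up(100 * self.national, 2)

    def band_pct(self) -> pd.Series:
        return self.national_by_band.map(lambda v: round_half_up(100 * v, 2))


def compute_coverage(
    beneficiaries: PanelTable | Sequence[PanelTable],
    population: PanelTable,
) -> CoverageTable:
    """Cell-wise beneficiaries / population.

    ``beneficiaries`` may be a sequence of monthly snapshots, in which case
    the cell-wise median is used; a single panel is used directly. A stratum
    with beneficiaries but zero population violates the panel invariant and
    raises.
    """
    if isinstance(beneficiaries, PanelTable):
        ben = beneficiaries.cells
    else:
        snaps = [b.cells for b in beneficiaries]
        if not snaps:
            raise ValueError("no beneficiary snapshots supplied")
        aligned = pd.concat(snaps, axis=1).fillna(0)
        ben = aligned.median(axis=1)
    pop, ben = population.cells.align(ben, fill_value=0)

    bad = (pop == 0) & (ben > 0)
    if bad.any():
        raise ValueError(
            f"beneficiaries with zero population at {list(pop.index[bad])[:3]}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = (ben / pop).fillna(0.0)

    band_num = ben.groupby(level="age_band").sum()
    band_den = pop.groupby(level="age_band").sum()
    national_by_band = (band_num / band_den.replace(0, np.nan)).fillna(0.0)
    total_pop = float(pop.sum())
    national = float(ben.sum()) / total_pop if total_pop else 0.0
    return CoverageTable(cells=cells, national_by_band=national_by_band,
                         national=national)


def legacy_private_estimate(
    sus_counts: CountsTable,
    coverage: CoverageTable,
    rounded: bool = True,
) -> CountsTable:
    """Legacy estimator: public-sector counts × insurance coverage, per cell.

    ``rounded`` applies half-up integer rounding per cell (the published
    table convention) before any summation; pass ``False`` for the exact
    product when studying error propagation.
    """
    counts, cov = sus_counts.cells.align(coverage.cells, join="left")
    if cov.isna().any():
        missing = list(cov.index[cov.isna()])[:3]
        raise ValueError(f"no coverage for strata {missing}")
    est = counts * cov
    if rounded:
        est = est.map(round_half_up)
    return CountsTable(est)


def estimated_reported_ratio(
    estimated: CountsTable, reported: CountsTable, ndigits: int = 2
) -> pd.DataFrame:
    """Ratio of coverage-based estimates to reported private counts.

    Values above 1 mean the legacy estimator over-reports. National and
    marginal ratios are formed from the corresponding totals; zero reported
    cells are undefined (NaN).
    """
    return estimated.ratio_to(reported, ndigits=ndigits)
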