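"""Record-level synthetic microdata whose aggregates match configured margins.

No study input can be redistributed at record level, so every pipeline stage
is exercised on generated microdata instead: public-sector admission records
with integer ages and five diagnosis slots, private-sector consolidated and
detail rows linked by care-event id, and the denominator panels. In
``exact`` mode the generated aggregates equal the configured margins cell
for cell (ages and field placement remain randomized but never cross a
selection boundary); ``multinomial`` mode draws cell totals from a
multinomial with the margin proportions, for sampling-noise studies.

Defaults reproduce the 2015 national study conditions
(:mod:`aicm.brazil2015`): the published public-sector UF × band grid, the
national private-sector margins under both case definitions, the within-band
age splits implied by the survey-age restriction, and a 23.8% withheld-ICD
rate among non-abortion obstetric filler events.

Decoy records — excluded ICD categories (O00–O02), non-obstetric diagnoses,
out-of-range ages, other years, unlinkable detail rows — are injected so
that selection rules are tested against realistic contamination; by
construction they never alter any selection output.

Randomness is confined to this module; the analysis pipeline itself is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import brazil2015
from .data_io import (
    COARSE_BANDS,
    CountsTable,
    MISSING_ICD_TOKEN,
    PanelTable,
    round_half_up,
)

__all__ = ["MarginSpec", "generate_sus", "generate_ans", "generate_panels",
           "generate_dataset"]

_ABORTION_CATS = ["O03", "O04", "O05", "O06", "O07", "O08"]
_EXCLUDED_CATS = ["O00", "O01", "O02"]
_BENIGN_CODES = ["O800", "O820", "O210", "Z349", "N939", "B349", "A090"]
_PROCEDURES = ["31309020", "31303013", "31309062"]
_OTHER_PROCEDURES = ["10101012", "31005012", "40304361"]


@dataclass
class MarginSpec:
    """Margins and noise parameters the generator must realize.

    ``noise_mode`` is ``exact`` (aggregates equal margins cell-for-cell) or
    ``multinomial`` (cell totals drawn with margin proportions).
    ``sus_share_18_19`` is the share of public-sector 10–19 admissions at
    ages 18–19; ``ans_share_15_19`` the share of private-sector 10–19 events
    in the 15–19 fine band; ``fine_upper_share`` splits the remaining
    decades into their upper fine band. ``icd_missing_rate`` is the share of
    non-abortion obstetric filler events whose ICD fields are all withheld
    (among abortion events the withheld-ICD share is fixed structurally by
    the two margins). ``decoy_fraction`` scales every decoy class.
    """

    sus_margins: CountsTable = field(default_factory=brazil2015.sus_margins)
    ans_margins_icd: CountsTable = field(
        default_factory=lambda: brazil2015.ans_margins("icd_only")
    )
    ans_margins_both: CountsTable = field(
        default_factory=lambda: brazil2015.ans_margins("icd_or_procedure")
    )
    population: PanelTable = field(default_factory=brazil2015.population_panel)
    beneficiaries: PanelTable = field(default_factory=brazil2015.beneficiaries_panel)
    births: PanelTable = field(default_factory=brazil2015.births_panel)
    sus_share_18_19: float = brazil2015.SUS_SHARE_18_19_WITHIN_10_19
    ans_share_15_19: float = brazil2015.ANS_SHARE_15_19_WITHIN_10_19
    fine_upper_share: float = 0.5
    icd_missing_rate: float = 0.238
    decoy_fraction: float = 0.02
    noise_mode: str = "exact"
    year: int = brazil2015.YEAR
    seed: int = 0

    def __post_init__(self):
        for name in ("sus_share_18_19", "ans_share_15_19", "fine_upper_share",
                     "icd_missing_rate", "decoy_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_mode not in ("exact", "multinomial"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")
        a, b = self.ans_margins_icd.reindex_union(self.ans_margins_both)
        if (a > b).any():
            raise ValueError(
                "icd_only margins exceed icd_or_procedure margins in some cell"
            )


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` with the given real quotas."""
    base = np.floor(quotas).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(quotas - base, kind="stable")
        i = 0
        while short < 0 and i < len(base):
            if base[order[i]] > 0:
                base[order[i]] -= 1
                short += 1
            i += 1
    return base


def _cell_counts(margins: CountsTable, rng: np.random.Generator,
                 noise_mode: str) -> pd.Series:
    cells = margins.cells
    if noise_mode == "exact" or cells.sum() == 0:
        return cells.astype(int)
    n = int(round(cells.sum()))
    p = (cells / cells.sum()).to_numpy()
    return pd.Series(rng.multinomial(n, p), index=cells.index)


# ---------------------------------------------------------------------------
# Public-sector admissions
# ---------------------------------------------------------------------------

def _random_icd(rng: np.random.Generator, cats: list[str]) -> str:
    cat = cats[rng.integers(len(cats))]
    return cat + (str(rng.integers(10)) if rng.random() < 0.5 else "")


def _random_icds(rng: np.random.Generator, cats: list[str], n: int) -> np.ndarray:
    """n random codes from the given categories, half carrying a subcode."""
    base = np.asarray(cats, dtype=object)[rng.integers(len(cats), size=n)]
    sub = rng.integers(10, size=n).astype(str).astype(object)
    return np.where(rng.random(n) < 0.5, base + sub, base)


def _diag_matrix(rng: np.random.Generator, codes: np.ndarray, width: int,
                 benign_rate: float = 0.0) -> np.ndarray:
    """Place each code in a random slot of a (n, width) empty matrix."""
    n = len(codes)
    diag = np.full((n, width), "", dtype=object)
    slot = rng.integers(width, size=n)
    diag[np.arange(n), slot] = codes
    if benign_rate:
        rows = np.flatnonzero(rng.random(n) < benign_rate)
        other = (slot[rows] + 1 + rng.integers(width - 1, size=len(rows))) % width
        benign = np.asarray(_BENIGN_CODES, dtype=object)[
            rng.integers(len(_BENIGN_CODES), size=len(rows))
        ]
        diag[rows, other] = benign
    return diag


def generate_sus(
    spec: MarginSpec | None = None,
    seed: int | None = None,
    noise_mode: str | None = None,
) -> pd.DataFrame:
    """Generate admission records realizing the public-sector margins.

    Each qualifying record carries an abortion-outcome ICD in one randomly
    chosen diagnosis slot (other slots empty or benign); ages are drawn
    within the record's band, with the 18–19 share of the 10–19 band
    allocated exactly (largest-remainder across regions) so the survey-age
    restriction is deterministic in exact mode. Decoy records that must not
    be selected are appended and the frame shuffled.
    """
    spec = spec or MarginSpec()
    seed = spec.seed if seed is None else seed
    noise_mode = noise_mode or spec.noise_mode
    rng = np.random.default_rng(seed)

    counts = _cell_counts(spec.sus_margins.to_coarse(), rng, noise_mode)

    # exact 18-19 allocation within the 10-19 band, across regions
    cells_1019 = counts[counts.index.get_level_values("age_band") == "10-19"]
    total_1019 = int(cells_1019.sum())
    target_18_19 = int(round_half_up(spec.sus_share_18_19 * total_1019))
    n18_by_cell = _largest_remainder(
        cells_1019.to_numpy() * (target_18_19 / total_1019) if total_1019 else
        np.zeros(len(cells_1019)),
        target_18_19,
    )
    n18_map = dict(zip(cells_1019.index, n18_by_cell))

    regions, ages = [], []
    for (region, band), n in counts.items():
        n = int(n)
        if n == 0:
            continue
        lo = int(band[:2])
        if band == "10-19":
            n18 = n18_map[(region, band)]
            a = np.concatenate([
                rng.integers(18, 20, size=n18),
                rng.integers(10, 18, size=n - n18),
            ])
        else:
            a = rng.integers(lo, lo + 10, size=n)
        regions.append(np.repeat(region, n))
        ages.append(a)

    n_total = int(counts.sum())
    region_arr = np.concatenate(regions) if regions else np.array([], dtype=object)
    age_arr = np.concatenate(ages) if ages else np.array([], dtype=int)

    diag = _diag_matrix(rng, _random_icds(rng, _ABORTION_CATS, n_total), 5,
                        benign_rate=0.15)

    frames = [pd.DataFrame({
        "region": region_arr, "age": age_arr,
        "diag1": diag[:, 0], "diag2": diag[:, 1], "diag3": diag[:, 2],
        "diag4": diag[:, 3], "diag5": diag[:, 4],
        "year": np.repeat(spec.year, n_total),
    })]

    # decoys: excluded ICDs, non-obstetric, out-of-range ages, wrong year
    n_decoy = max(20, int(spec.decoy_fraction * n_total)) if spec.decoy_fraction else 0
    pool = spec.sus_margins.regions
    if n_decoy:
        def decoy_frame(n, ages_fn, codes, year):
            d = _diag_matrix(rng, codes, 5)
            return pd.DataFrame({
                "region": rng.choice(pool, size=n),
                "age": ages_fn(n),
                "diag1": d[:, 0], "diag2": d[:, 1], "diag3": d[:, 2],
                "diag4": d[:, 3], "diag5": d[:, 4],
                "year": np.repeat(year, n),
            })

        in_range = lambda n: rng.integers(10, 50, size=n)
        benign = lambda n: np.asarray(_BENIGN_CODES, dtype=object)[
            rng.integers(len(_BENIGN_CODES), size=n)
        ]
        outside = lambda n: np.where(
            rng.random(n) < 0.5, rng.integers(0, 10, size=n),
            rng.integers(50, 90, size=n))
        half = n_decoy // 2 + 1
        frames.append(decoy_frame(
            n_decoy, in_range, _random_icds(rng, _EXCLUDED_CATS, n_decoy), spec.year))
        frames.append(decoy_frame(n_decoy, in_range, benign(n_decoy), spec.year))
        frames.append(decoy_frame(
            half, outside, _random_icds(rng, _ABORTION_CATS, half), spec.year))
        frames.append(decoy_frame(
            half, in_range, _random_icds(rng, _ABORTION_CATS, half), spec.year + 1))

    out = pd.concat(frames, ignore_index=True)
    return out.iloc[rng.permutation(len(out))].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Private-sector events
# ---------------------------------------------------------------------------

def _fine_split(
    counts: pd.Series, share_15_19: float, upper_share: float,
    rng: np.random.Generator,
) -> pd.Series:
    """Split coarse-band cell counts onto fine bands (largest remainder)."""
    out = {}
    for band in COARSE_BANDS:
        cells = counts[counts.index.get_level_values("age_band") == band]
        total = int(cells.sum())
        if total == 0:
            continue
        share = share_15_19 if band == "10-19" else upper_share
        target_upper = int(round_half_up(share * total))
        upper_alloc = _largest_remainder(
            cells.to_numpy() * (target_upper / total), target_upper
        )
        lo = int(band[:2])
        lower_band, upper_band = f"{lo}-{lo + 4}", f"{lo + 5}-{lo + 9}"
        for (region, _), n, nu in zip(cells.index, cells.to_numpy(), upper_alloc):
            if n - nu:
                out[(region, lower_band)] = out.get((region, lower_band), 0) + (n - nu)
            if nu:
                out[(region, upper_band)] = out.get((region, upper_band), 0) + int(nu)
    return pd.Series(out, dtype=int)


def generate_ans(
    spec: MarginSpec | None = None,
    seed: int | None = None,
    noise_mode: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate linked consolidated and detail tables realizing both margins.

    Three event kinds are built per cell: ICD-only (abortion ICD in a random
    field), ICD+procedure (shared event id appearing in both tables — the
    deduplication stress), and procedure-only (all ICD fields withheld plus
    a qualifying detail row); cell counts are chosen so the ICD-only and
    ICD-or-procedure case definitions reproduce their respective margins.
    Excluded-ICD decoys with qualifying procedures, benign obstetric filler
    (withheld ICDs at ``icd_missing_rate``), duplicated detail rows and a
    few unlinkable detail rows are added; none may change any selection.
    """
    spec = spec or MarginSpec()
    seed = spec.seed if seed is None else seed
    noise_mode = noise_mode or spec.noise_mode
    rng = np.random.default_rng(seed + 1)

    both = _cell_counts(spec.ans_margins_both.to_coarse(), rng, noise_mode)
    if noise_mode == "exact":
        icd = spec.ans_margins_icd.to_coarse().cells.astype(int)
        icd, both = icd.align(both, fill_value=0)
    else:  # binomial thinning keeps icd <= both cellwise
        icd_m, both_m = spec.ans_margins_icd.reindex_union(spec.ans_margins_both)
        with np.errstate(invalid="ignore"):
            p = (icd_m / both_m.replace(0, np.nan)).fillna(0.0)
        p = p.reindex(both.index).fillna(0.0)
        icd = pd.Series(
            rng.binomial(both.to_numpy().astype(int), p.to_numpy()), index=both.index
        )

    fine = _fine_split(both.astype(int), spec.ans_share_15_19,
                       spec.fine_upper_share, rng)

    cons_rows: list[tuple] = []
    det_rows: list[tuple] = []
    eid = 0

    def new_id() -> str:
        nonlocal eid
        eid += 1
        return f"E{eid:07d}"

    # expand fine cells back into per-coarse pools so icd/proc-only kinds
    # are assigned within each coarse cell
    fine_by_coarse: dict[tuple[str, str], list[str]] = {}
    for (region, fband), n in fine.items():
        lo = (int(fband[:2]) // 10) * 10
        key = (region, f"{lo}-{lo + 9}")
        fine_by_coarse.setdefault(key, []).extend([fband] * int(n))

    for key, n_both in both.astype(int).items():
        if n_both == 0:
            continue
        region, band = key
        n_icd = int(icd.get(key, 0))
        bands = fine_by_coarse.get(key, [band] * n_both)
        rng.shuffle(bands)
        for i in range(n_both):
            ev = new_id()
            fband = bands[i]
            icds: list[str | None] = ["", "", "", ""]
            if i < n_icd:
                icds[rng.integers(4)] = _random_icd(rng, _ABORTION_CATS)
                if rng.random() < 0.3:  # ICD+procedure: dedup stress
                    det_rows.append((ev, _PROCEDURES[rng.integers(3)]))
            else:  # procedure-only: ICD withheld
                icds = [None, None, None, None]
                det_rows.append((ev, _PROCEDURES[rng.integers(3)]))
            if rng.random() < 0.2:  # unrelated procedure on the same event
                det_rows.append((ev, _OTHER_PROCEDURES[rng.integers(3)]))
            cons_rows.append((ev, region, fband, *icds, spec.year))

    # decoys
    n_total = int(both.sum())
    n_decoy = max(10, int(spec.decoy_fraction * n_total)) if spec.decoy_fraction else 0
    pool = spec.ans_margins_both.regions
    fine_bands = [b for b in ("15-19", "20-24", "25-29", "30-34", "35-39")]
    for _ in range(n_decoy):
        # excluded category, often with a qualifying procedure: must not count
        ev = new_id()
        icds = ["", "", "", ""]
        icds[rng.integers(4)] = _random_icd(rng, _EXCLUDED_CATS)
        cons_rows.append((ev, pool[rng.integers(len(pool))],
                          fine_bands[rng.integers(len(fine_bands))], *icds, spec.year))
        if rng.random() < 0.7:
            det_rows.append((ev, _PROCEDURES[rng.integers(3)]))
    for _ in range(n_decoy):
        # benign obstetric filler; ICDs withheld at the configured rate
        ev = new_id()
        if rng.random() < spec.icd_missing_rate:
            icds = [None, None, None, None]
        else:
            icds = ["", "", "", ""]
            icds[rng.integers(4)] = _BENIGN_CODES[rng.integers(len(_BENIGN_CODES))]
        cons_rows.append((ev, pool[rng.integers(len(pool))],
                          fine_bands[rng.integers(len(fine_bands))], *icds, spec.year))
        det_rows.append((ev, _OTHER_PROCEDURES[rng.integers(3)]))
    for _ in range(max(3, n_decoy // 10)):
        # detail rows with no consolidated counterpart (unlinkable)
        det_rows.append((f"X{rng.integers(10**6):06d}", _PROCEDURES[rng.integers(3)]))

    # duplicate a sample of detail rows: idempotence stress
    if det_rows:
        k = max(1, len(det_rows) // 20)
        det_rows.extend(det_rows[i] for i in rng.integers(len(det_rows), size=k))

    cons = pd.DataFrame(
        cons_rows,
        columns=["event_id", "region", "age_band", "icd1", "icd2", "icd3", "icd4",
                 "year"],
    )
    det = pd.DataFrame(det_rows, columns=["event_id", "procedure_code"])
    cons = cons.iloc[rng.permutation(len(cons))].reset_index(drop=True)
    det = det.iloc[rng.permutation(len(det))].reset_index(drop=True)
    return cons, det


# ---------------------------------------------------------------------------
# Panels and full datasets
# ---------------------------------------------------------------------------

def generate_panels(spec: MarginSpec | None = None) -> dict[str, PanelTable]:
    """Denominator panels consistent with the configured margins.

    Panels are deterministic copies of the margin tables (population,
    beneficiaries, live births); the generator's randomness never touches
    denominators.
    """
    spec = spec or MarginSpec()
    return {
        "population": spec.population,
        "beneficiaries": spec.beneficiaries,
        "births": spec.births,
    }


def generate_dataset(
    spec: MarginSpec | None = None,
    outdir: str | Path = ".",
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the five CSV inputs of a full run; returns their paths."""
    spec = spec or MarginSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sus = generate_sus(spec, seed=seed)
    cons, det = generate_ans(spec, seed=seed)
    cons = cons.copy()
    for c in ("icd1", "icd2", "icd3", "icd4"):
        cons[c] = cons[c].map(lambda v: MISSING_ICD_TOKEN if v is None else v)
    panels = generate_panels(spec)
    paths = {
        "sus": outdir / "sus_admissions.csv",
        "ans_cons": outdir / "ans_cons.csv",
        "ans_det": outdir / "ans_det.csv",
        "population": outdir / "population.csv",
        "beneficiaries": outdir / "beneficiaries.csv",
        "births": outdir / "births.csv",
    }
    sus.to_csv(paths["sus"], index=False)
    cons.to_csv(paths["ans_cons"], index=False)
    det.to_csv(paths["ans_det"], index=False)
    panels["population"].write_csv(paths["population"])
    panels["beneficiaries"].write_csv(paths["beneficiaries"])
    panels["births"].write_csv(paths["births"])
    return paths
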