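"""Canonical national inputs for the 2015 Brazilian run.

These constants are the published administrative aggregates and survey
parameters the national analysis consumes: public-sector (SIH/SUS)
abortion-hospitalization counts by federative unit (UF) and decade age band,
the national private-sector (ANS) counts by band under the ICD-only and
ICD-or-procedure definitions, the national female population and
health-insurance beneficiary counts by band, the ballot-box survey (PNA)
calibration parameters, and the band-level insurance coverages used to split
denominators by funding sector.

Regional ANS / coverage detail is deliberately not carried here: only cells
whose published values are unambiguous are packaged, and the national rows
suffice for every national indicator. The live-birth split by maternal age
band was not published; :data:`SYNTHETIC_BIRTHS_BY_BAND` is a synthetic
split, constrained to the published total and sector margin.
"""

from __future__ import annotations

from .data_io import COARSE_BANDS, CountsTable, PanelTable

YEAR = 2015

# ---------------------------------------------------------------------------
# Public-sector (SIH/SUS) abortion hospitalizations, by UF × decade band
# ---------------------------------------------------------------------------

#: (10-19, 20-29, 30-39, 40-49) hospitalization counts per UF, 2015.
SUS_HOSPITALIZATIONS_BY_UF: dict[str, tuple[int, int, int, int]] = {
    "AC": (249, 510, 322, 66),
    "AL": (686, 1358, 781, 167),
    "AM": (616, 1242, 747, 173),
    "AP": (252, 677, 434, 78),
    "BA": (2264, 5528, 4100, 772),
    "CE": (1332, 3460, 2405, 618),
    "DF": (264, 726, 661, 147),
    "ES": (374, 991, 730, 179),
    "GO": (538, 1384, 927, 175),
    "MA": (1123, 2498, 1216, 186),
    "MG": (2036, 5699, 4453, 1065),
    "MS": (282, 620, 417, 78),
    "MT": (324, 774, 450, 91),
    "PA": (1467, 3028, 1396, 264),
    "PB": (639, 1520, 1156, 250),
    "PE": (1612, 3751, 2441, 519),
    "PI": (467, 1001, 618, 127),
    "PR": (759, 1887, 1384, 374),
    "RJ": (2049, 5160, 3452, 699),
    "RN": (549, 1269, 898, 218),
    "RO": (268, 737, 424, 88),
    "RR": (173, 448, 282, 50),
    "RS": (663, 1783, 1575, 445),
    "SC": (454, 1286, 1034, 231),
    "SE": (522, 1243, 857, 169),
    "SP": (3602, 10122, 7699, 2011),
    "TO": (348, 786, 460, 95),
}

# ---------------------------------------------------------------------------
# Private-sector (ANS) abortion hospitalizations, national, by decade band
# ---------------------------------------------------------------------------

#: events carrying an abortion ICD (O03–O08) in any field, none of O00–O02.
ANS_ICD_ONLY_BY_BAND: dict[str, int] = {
    "10-19": 314, "20-29": 3287, "30-39": 5188, "40-49": 1011,
}

#: events with an abortion ICD and/or an abortion procedure (deduplicated).
ANS_ICD_OR_PROCEDURE_BY_BAND: dict[str, int] = {
    "10-19": 669, "20-29": 6696, "30-39": 11181, "40-49": 2210,
}

# ---------------------------------------------------------------------------
# Denominator panels, national, by decade band
# ---------------------------------------------------------------------------

FEMALE_POPULATION_BY_BAND: dict[str, int] = {
    "10-19": 16_284_480, "20-29": 16_995_533,
    "30-39": 16_826_200, "40-49": 13_762_740,
}

INSURANCE_BENEFICIARIES_BY_BAND: dict[str, int] = {
    "10-19": 2_921_759, "20-29": 4_489_047,
    "30-39": 5_386_943, "40-49": 3_733_093,
}

LIVE_BIRTHS_TOTAL = 3_017_203
SUPPLEMENTARY_LIVE_BIRTHS = 796_198  # published sector margin

#: SYNTHETIC split of the 2015 live births by maternal age band. Only the
#: total (3,017,203) and the supplementary-sector margin (796,198) were
#: published; this split was constructed once to satisfy both under the
#: band coverages below, with a realistic maternal-age profile.
SYNTHETIC_BIRTHS_BY_BAND: dict[str, int] = {
    "10-19": 541_763, "20-29": 1_510_000, "30-39": 908_237, "40-49": 57_203,
}

#: health-insurance coverage by age band used to split population and
#: live-birth denominators into supplementary vs public sectors.
BAND_COVERAGE: dict[str, float] = {
    "10-19": 0.18, "20-29": 0.26, "30-39": 0.32, "40-49": 0.27,
}

# ---------------------------------------------------------------------------
# Survey (PNA 2016) calibration parameters
# ---------------------------------------------------------------------------

#: women estimated to have had an abortion in 2015 (national ballot-box survey).
PNA_TOTAL_ABORTIONS = 503_000

#: survey-wide annual abortion frequency among women 18–39.
PNA_ANNUAL_FREQUENCY = 0.0135

#: share of 15–19 private-sector hospitalizations attributed to ages 18–19
#: (the survey covers 18–39 but the claims data only provide 15–19).
SHARE_18_19_OF_15_19 = 0.75

#: women 18–39 by funding sector, back-solved from the survey's sector
#: abortion estimates at the 1.35% frequency (the published sector scenario).
SECTOR_POPULATION_18_39 = {
    "sus": round(371_208 / PNA_ANNUAL_FREQUENCY),          # 27,496,889
    "supplementary": round(128_803 / PNA_ANNUAL_FREQUENCY),  # 9,540,963
}

# ---------------------------------------------------------------------------
# Within-band age detail implied by the survey-age restriction
# ---------------------------------------------------------------------------

#: share of public-sector 10–19 hospitalizations at ages 18–19 (16,625 of
#: 23,912), the value consistent with the published 18–39 sector total.
SUS_SHARE_18_19_WITHIN_10_19 = 16_625 / 23_912

#: share of private-sector 10–19 hospitalizations in the 15–19 fine band
#: (641 of 669), consistent with the published 18–39 sector total under the
#: 75% rule.
ANS_SHARE_15_19_WITHIN_10_19 = 641 / 669

# ---------------------------------------------------------------------------
# Final correction factors (complications without hospitalization)
# ---------------------------------------------------------------------------

#: point factor and (lower, upper) bounds per sector.
COMPLICATION_FACTORS = {
    "sus": (4, (3, 5)),
    "supplementary": (5, (4, 6)),
}


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------

def sus_margins() -> CountsTable:
    """Public-sector hospitalization counts, UF × decade band."""
    return CountsTable.from_dict(
        {
            (uf, band): n
            for uf, row in SUS_HOSPITALIZATIONS_BY_UF.items()
            for band, n in zip(COARSE_BANDS, row)
        }
    )


def ans_margins(mode: str = "icd_or_procedure", region: str = "BR") -> CountsTable:
    """National private-sector counts under either case definition."""
    if mode == "icd_only":
        return CountsTable.from_band_totals(ANS_ICD_ONLY_BY_BAND, region)
    if mode == "icd_or_procedure":
        return CountsTable.from_band_totals(ANS_ICD_OR_PROCEDURE_BY_BAND, region)
    raise ValueError(f"unknown mode {mode!r}")


def population_panel(region: str = "BR") -> PanelTable:
    return PanelTable.from_band_totals(
        FEMALE_POPULATION_BY_BAND, region, kind="population"
    )


def beneficiaries_panel(region: str = "BR") -> PanelTable:
    return PanelTable.from_band_totals(
        INSURANCE_BENEFICIARIES_BY_BAND, region, kind="beneficiaries"
    )


def births_panel(region: str = "BR") -> PanelTable:
    """Live births by maternal age band (synthetic split, published margins)."""
    return PanelTable.from_band_totals(
        SYNTHETIC_BIRTHS_BY_BAND, region, kind="live_births"
    )
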