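# Methods

## The model

The pipeline estimates induced abortions indirectly from hospitalized
abortion complications, per funding sector:

    abortions_s = hospitalizations_s × f_miscarriage(age) × f_complications_s

Assumptions inherited from the indirect method:

- every induced abortion with a hospitalized complication appears in one of
  the two claims systems with a qualifying diagnosis or procedure;
- the age profile of miscarriage-related hospitalizations is captured by
  three fixed factors (0.90 under 30, 0.85 at 30–39, 0.75 at 40–49);
- the external survey total of women reporting an abortion is an unbiased
  proxy for the number of abortions (one per woman per year);
- uncertainty is summarized only by shifting the complications factor ±1;
  no sampling-based interval is defined.

## Case selection

Public sector: a hospitalization qualifies if any of its five diagnosis
fields carries a category in O03–O08, the woman is 10–49, and the year
matches. Categories O00–O02 are not selection criteria; a record carrying
both an abortion category and an excluded category **is counted** by
default, because the public-sector rule is stated purely as an inclusion
rule. A `SelectionRule(exclude_in_sus=True)` switch applies the exclusion
symmetrically for sensitivity analysis. The unit is the hospitalization;
readmissions are not collapsed (the source systems do not identify women).

Private sector: consolidated and detail rows are joined on the care-event
id; flags are computed over all ICD fields and all procedure rows of an
event, so duplicated detail rows are idempotent. An event counts under
`icd_only` if it has an abortion category and no excluded category, and
under `icd_or_procedure` if it has an abortion category *or* a qualifying
procedure (and no excluded category). Detail rows whose event id never
appears in the consolidated table have no region or age band; they are
excluded from stratified tables and surfaced in a diagnostics count —
the conservative choice, since assigning them to any stratum would be
invention.

## Rounding

Printed-table arithmetic is reproduced with half-up rounding (ties away
from zero) at each printed intermediate: per band for corrected
hospitalizations, at sector totals for the survey-age restriction, integers
for abortion estimates, one decimal for factors and indicators, two for
coverage percentages and the estimated/reported ratio. Two conventions
matter and are implemented deliberately:

- **Equal-factor pooling.** Bands sharing a miscarriage factor are pooled
  before rounding and reported under a merged label (10–19 and 20–29 at
  0.90 become the 10–29 row). This is visible only at exact .5 products —
  e.g. 7,365 × 0.90 = 6,628.5 → 6,629 — and is how the published tables
  are internally consistent.
- **Decimal arithmetic.** Products of counts with decimal factors are
  computed in `Decimal`, not binary floats, so .5 ties are exact. An
  unrounded mode (`rounded=False`, `rounding: exact` in configs) exists for
  propagation studies.

National aggregates are always formed from summed numerators and
denominators, never by averaging percentages or ratios.

## Scenario calibration of the complications factor

The survey covers women 18–39, so hospitalizations are restricted to that
range first: public-sector records are filtered on integer age; the
private-sector age detail stops at 5-year bands, so 75% of the 15–19 band
is attributed to ages 18–19 (`share_18_19`, configurable — survey data show
abortion frequency rising steeply across 15–19, so the 18–19 share exceeds
the population share). Miscarriage factors are applied (0.90 under 30,
0.85 at 30–39) and each sector total is rounded once.

Three scenario modes over the survey parameters (503,000 women reporting an
abortion in 2015; 1.35% annual frequency):

- **pooled** — one factor: survey total ÷ total hospitalizations;
- **sector** — explicit frequencies per sector: estimated abortions are
  population × frequency, factor = estimate ÷ hospitalizations;
- **constrained** — the supplementary frequency is a fixed fraction k of
  the public one (0.50/0.75/0.90 in the canonical suite); the one unknown
  frequency solves Σ_s pop_s × freq_s = survey total, linearly.

The sector populations of women 18–39 are **explicit inputs**, not derived
from the coverage module: applying the quoted band coverages to census
populations gives a supplementary population near 10.4M, which is not
consistent with the published sector abortion estimates; back-solving those
estimates at the 1.35% frequency gives 27,496,889 (public) and 9,540,963
(supplementary), and these values reproduce the published constrained-mode
outputs exactly. The discrepancy is a property of the source estimates, and
the back-solved pair is carried as the canonical default.

The final factors adopted for estimation are 4 (range 3–5) for the public
sector and 5 (range 4–6) for the supplementary sector — the supplementary
point value reflects the most conservative scenario, in which insured women
abort at half the frequency of uninsured women.

## Denominators

The supplementary population (and live births) is the coverage-weighted
band sum (coverages 18% / 26% / 32% / 27% by decade band), rounded half-up;
the public-sector denominator is *defined* as total minus supplementary, so
sectors always add up exactly. If births by maternal age band are not
available, a config option accepts pre-split totals.

## The synthetic-data generator

The generator emulates the study inputs at record level so that no real
download is needed anywhere. Defaults are the 2015 national study
conditions: the full public-sector UF × band grid (134,054 admissions), the
national private-sector margins under both case definitions (9,800 /
20,756), the national population, beneficiary and live-birth panels, and
the within-band splits implied by the survey-age restriction (16,625 of
23,912 public 10–19 admissions at ages 18–19; 641 of 669 private 10–19
events in the 15–19 band — each the unique integer consistent with the
published 18–39 sector totals under the stated rounding).

In `exact` mode the selected aggregates equal the margins cell for cell:
counts, the 18–19 allocation (largest-remainder across regions) and the
fine-band split are deterministic, while ages within bands, ICD subcodes,
field placement and decoys remain seed-dependent. `multinomial` mode draws
cell totals from a multinomial (with binomial thinning keeping the ICD-only
counts below the combined counts cell-wise) for sampling-noise studies.

The live-birth age split is synthetic: only the total (3,017,203) and the
supplementary margin (796,198) are published, and the packaged split was
constructed once to satisfy both under the band coverages, with a
plausible maternal-age profile.

What the generator does **not** emulate: municipality structure and
seasonality; realistic co-morbidity patterns in the unused diagnosis
fields; the UF-level variation in withheld ICDs (the 23.8% obstetric
underreporting rate is applied only to non-abortion filler events — among
abortion events the withheld share is fixed structurally by the two
margins); duplicate admissions of the same woman. Passing tests therefore
demonstrate that the pipeline arithmetic and selection logic are correct
under the published margins, not that the selection rules would be robust
to coding practices unobserved in those margins.

## Numerical and degenerate-input choices

- Zero denominators in ratio tables are undefined cells (NaN, printed "-"),
  not errors; zero denominators in the rate/ratio indicators are errors.
- Empty inputs yield zero tables, not errors.
- A factor requested with zero hospitalizations raises
  `UndefinedFactorError`.
- Largest-remainder allocations break ties by stable cell order, so runs
  are bit-reproducible for a given seed.
- Problem sizes: tests and the acceptance script run at the full national
  scale (≈142,000 public-sector records, ≈22,000 private-sector events);
  the complete run takes a few seconds.

## Known limitations

- Regional (per-UF) private-sector margins and coverage cells are not
  packaged — only nationally aggregated private-sector results are
  reproduced; the public-sector grid is full-resolution.
- The ±1-factor bounds understate true uncertainty; they ignore sampling
  error in the survey total and any misclassification in claims coding.
- The miscarriage factors treat 30–34 like 35–39 (the private-sector data
  provide only the 30–39 band), likely overcorrecting at 30–34.
- Out-of-pocket private hospitalizations appear in neither claims system
  and are structurally missed by the method.
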