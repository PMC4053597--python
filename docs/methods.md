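# Methods

## Study design and estimand

The pipeline implements a cohort analysis of person-time at risk.  Every
member of an elderly cohort (born before 1945, alive at the start of
2005) is followed from 2005-01-01 until the first of: first hip
fracture, death, emigration, or 2010-12-31, all end days inclusive.
Follow-up days are classified as *exposed* or *unexposed* to a drug
group, and the estimand is the ratio of the fracture rate on exposed
days to the rate on comparable unexposed days.

Comparability is achieved by indirect standardization.  Within strata
*s* defined by sex × single birth year × two-month calendar bin,

    rate_s = events_unexposed_s / person_days_unexposed_s
    E      = Σ_s rate_s · person_days_exposed_s
    SIR    = O / E

where *O* is the number of fractures observed on exposed days.  The
stratification absorbs the three dominant determinants of both fracture
risk and drug use in such cohorts: sex, age, and secular/seasonal time.
Unexposed person-time of a group-G analysis is all follow-up time not
exposed to G; time exposed to *other* studied groups stays in the
reference by default (co-exposure is a recognised feature of these
cohorts), with a mutually-exclusive sensitivity switch
(`exclusive_exposure`) that excises other-group days from the reference
entirely.

The attributable risk is AR = (O − E) / N, with N all first fractures
in the analysis population — the fraction of all fractures attributable
to the exposure, negative if exposure is protective.

## Exposure model

Dispensing registries record purchases, not intake, so exposed duration
is an explicit assumption.  Each dispensing opens a closed window
starting on the purchase day, with length given by a selectable policy:

* `fixed_days` ∈ {3, 7, 14} — a fixed window regardless of quantity;
* `ddd_days` — `ceil(n_DDD / f)` days at an assumed daily consumption
  of f ∈ {0.5, 1.0} DDD/day (a defined daily dose is the assumed
  average adult maintenance dose; actual prescribed daily doses in
  elderly populations are typically below 1.0 DDD, so f = 1.0 yields
  conservative, f = 0.5 generous, exposure durations).

Other values are accepted but flagged as unconventional.  Windows of
one person and group merge by day-set union — overlapping or adjacent
windows coalesce and there is no stockpiling of leftover supply.  A
fracture on the purchase day counts as exposed.  Windows are truncated
to follow-up only during tabulation, keeping exposure construction
independent of outcome data.

**Recently started use** is the first 14 days of an exposure run whose
start is preceded by 360 days without a single exposed day to the same
group ("the drug in question"); a `washout_scope="any"` switch applies
the stricter any-studied-drug washout.  The washout clock runs on
exposed days, not dispensing dates, so a long DDD-derived tail blocks
"recent" status.  Two edge cases the design leaves open are resolved
as: (1) an exposure run shorter than 14 days caps the recent window at
the run length (counted in diagnostics); (2) a candidate whose washout
interval reaches back before the start of the available dispensing
history (2004-01-01) cannot be verified and is skipped, also counted.

## Numerical implementation

Tabulation is exact integer interval algebra on day numbers: per-person
follow-up and window intervals are intersected with the fixed calendar
bins, so no per-day data structure is ever materialised in production.
A deliberately naive per-day enumeration (`brute_force_tabulate`) with
the identical contract serves as the oracle; the two agree cell-for-cell
on random cohorts under every policy (tested, exact equality).  Events
land in the cell of their event date; the fracture day itself
contributes one person-day, so every event lives in a cell with
nonzero person-time.  Ties among follow-up end reasons resolve
fracture > death > emigration > study end (the choice is immaterial for
person-time).

The 95% interval for the SIR treats O as Poisson with E fixed and uses
the exact bounds in chi-square-quantile form,

    low  = χ²(α/2, 2O) / 2 / E        (0 when O = 0)
    high = χ²(1 − α/2, 2O + 2) / 2 / E

the conservative standard for standardized ratios; Byar's approximation
is available via `method="byar"` for comparison and agrees to a few per
mille at O ≳ 100.  O = 0 yields a zero estimate with the one-sided
upper bound −ln(α/2)/E.  E = 0 is undefined and raises; the pipeline
converts this into a "not estimable" result (counts reported, estimate
NaN) rather than aborting, because sparse subsets (e.g. a small birth
cohort) legitimately produce it at desk scale.  Strata with exposed but
no unexposed person-time cannot contribute an expectation; they
contribute zero and are counted in every result.

Birth-year adjustment uses single calendar years; the report layer
re-bins to presentation cohorts (1935–44, 1925–34, 1915–24, <1915),
which partition the cohort so their observed counts sum to the total.
Calendar bins are fixed two-month partitions (Jan–Feb, Mar–Apr, …), not
rolling windows.

## Diurnal subanalysis

Fracture clock times classify events as night (20:00–07:59) or day
(08:00–19:59); missing times are excluded from numerator and rates
alike (complete case).  Person-day denominators are full days for both
classes — the class split enters only through event counts.  Since both
classes span twelve hours, a half-day denominator convention would
rescale rate_s and E by the same factor and cancel from O/E; the
convention is therefore stated, not consequential.  One exact identity
follows and is tested: E_day + E_night equals E computed from
known-time events.  Under clock times missing completely at random the
class-specific SIRs are unbiased; this is checked by simulation against
full-data estimates.

## Synthetic registry generator

The generator produces the three registry tables with known ground
truth, emulating the statistical structure the analysis assumes:

* **Cohort** — birth years from a truncated normal (mean 1932.2,
  sd 8.9, range 1905–1944: mean age ≈ 73 at entry), 56% women;
  mortality Gompertz in attained age, h(a) = 5.5·10⁻⁵·e^{0.09a}/yr
  (≈ 30% die over the six years); emigration a constant 0.1%/yr.
* **Dispensings** — ever-user indicators per group (23% anxiolytics,
  30% hypnotics; optionally age-dependent via a log-odds slope, to
  generate confounding by age); substances drawn from a per-group menu
  so that classification into subgroups is exercised end to end.  Users
  are prevalent (first observed dispensing in the 2004 history year)
  with probability 0.35/0.60 for anxiolytics/hypnotics, otherwise
  incident during follow-up; refills follow a renewal process with
  per-user lognormal mean gaps (median 110/45 days), quantities from
  {10, 25, 50, 100} DDD.  These intensities were fixed so that the
  share of fractures occurring during exposure (≈ 5% anxiolytics,
  ≈ 14% hypnotics under the 1.0-DDD proxy) matches what such registry
  cohorts show: intermittent anxiolytic use, chronic nightly hypnotic
  use.  Dispensings stop at death/emigration.
* **Fractures** — a first-event piecewise-constant hazard: baseline
  Gompertz h(a) = 4.4·10⁻⁶·e^{0.10a}/yr (≈ 5% cumulative incidence),
  multiplied on exposed days by the group's rate ratio.  The diurnal
  mixture puts P(day) = 2/3 of events in daytime; class-specific
  ratios ρ_day, ρ_night tilt both the total hazard
  (ρ_overall = P_day·ρ_day + P_night·ρ_night, exactly the estimand of
  the overall SIR) and the clock-time class of exposed events.  Clock
  times are recorded with probability 0.51, missing completely at
  random.  Event days come from exact inversion of the cumulative
  hazard over the person's breakpoint segments, so the generator is
  fully vectorised and deterministic given the seed.

Defaults place the true overall rate ratios at 1.4 (anxiolytics) and
1.2 (hypnotics).  The default desk-scale cohort is 50,000 persons
(≈ 100 million person-days); the acceptance studies use 50,000, or
100,000 for the diurnal recovery study where class-specific event
counts are the limiting factor.

**What the generator does not emulate** — and what passing tests
therefore cannot show about real data: informative censoring (death and
fracture risk are conditionally independent given age), nursing-home
misclassification of exposure, under-ascertainment of fractures in
early registry years, dose–response or pharmacokinetic carry-over,
within-person seasonality of drug use, and any correlation between
clock-time missingness and event characteristics.  Confounding exists
only through age unless the age coefficient is switched on; real
cohorts confound through health status in ways no sex/age/period
stratification removes.

## Verification strategy

Beyond unit tests, the end-to-end properties checked on seeded
replicates are: CI calibration under ρ = 1 (coverage of 1.0), recovery
of ρ = 1.5 within ±0.15 with CI coverage, stratified-beats-crude under
age confounding, diurnal recovery (ρ_night = 1.3 > ρ_day = 1.1 with 51%
known times; the sign per replicate, the ±0.15 accuracy on the mean
over 20 replicates, where the per-replicate Monte-Carlo sd of the night
estimate is itself ≈ 0.12), exact washout windows on a hand-derived
six-person fixture, and the Poisson bounds against an independent
gamma-quantile formulation.

## Known limitations

Single-year × two-month stratification is sparse at desk scale; small
subsets can be non-estimable (reported, not fabricated).  The recent-use
subanalysis at n = 50,000 yields very few exposed events and serves to
exercise the logic, not to estimate precisely.  The CLI reads the whole
registry into memory; cohorts beyond ~10⁷ persons would need chunked
I/O.  The classification table covers the studied substances plus an
ATC-prefix fallback, not the full ATC ontology.
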