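# Methods

This note documents the statistical machinery, the synthetic-cohort
model, the numerical choices, and the limits of what the test suite can
establish.

## Records, quarters and pairing

An assessment record is one row of coded items (integer ordinal codes
or numeric vitals; the empty string is the missing token in CSV) plus
identity fields: person, facility, sector (CCC or LTC), assessment type
(admission / quarterly / annual), reference date, sign-off date and
birthdate.  Records assessed as comatose are excluded before any
scoring or audit.

Quarters are calendar quarters (Jan–Mar = Q1), labelled `YYYY_Q`.  The
label scheme is anchored to the calendar, not the fiscal year; a
sector's quarter index counts calendar quarters from its first observed
quarter.  Longitudinal analyses use consecutive within-person,
within-sector pairs ordered by reference date; stays and readmissions
are not modelled separately — the person×sector chain alone defines
adjacency.  Pairs whose two reference dates fall in the same calendar
quarter are dropped from pair-level audits (a reassessment is compared
against a previous quarter).  Duplicate (person, sector, date) rows are
a fatal input error.

## Scales

Scale definitions follow the cited instruments:

* **ADL Long Form** — sum of 7 self-performance items (bed mobility,
  transfer, locomotion, dressing, eating, toilet use, personal
  hygiene), each 0–4 with 8 ("activity did not occur") recoded to 4 —
  the maximal-dependence interpretation.  Range 0–28.
* **DRS** — sum of 7 mood items, each 0/1/2.  Range 0–14.
* **ABS** — sum of 4 behaviour items, each 0–3.  Range 0–12.
* **CPS** — decision tree: comatose → 6; severely impaired
  decision-making (code 3) → 5, or 6 with totally dependent eating;
  otherwise count impairments (memory problem, any decision-making
  impairment, any problem being understood): 0 → 0, 1 → 1, ≥ 2 → 2 plus
  the number of severe impairments (decision-making ≥ 2, understood
  ≥ 2).  The severe-decision-making override sits above the count
  branches, which the exhaustive-grid tests pin down.
* **RUG-ADL** — bed mobility, transfer and toilet use each recode to
  1/3/4 (self-performance ≤ 1 / = 2 / ≥ 3), raised to 5 when the paired
  support item shows two-or-more-person assistance (support ≥ 3);
  eating recodes to 1/2/3.  Range 4–18.
* **Pain Scale** — 0 no pain, 1 less-than-daily, 2 daily, 3 daily and
  severe.

A missing required item makes the score missing, and the dichotomy
flags (CPS 3+, RUG-ADL 11+, ABS 5+, DRS 3+) missing with it.  Each
scale has a scalar reference implementation and a vectorized one; the
suite asserts their equivalence on sampled cohorts, so the fast path
cannot drift from the readable one.

## Audit rules

Cross-sectional rules flag, per record: mood persistence coded present
with all 16 mood items absent; exactly one member of an ADL
performance/support pair coded 8; a parenteral/IV or feeding-tube route
with zero calorie and fluid intake codes, **or** intake codes without a
route (the mismatch is flagged in both directions); an ulcer stage
assigned with the count at that stage missing or zero; therapy days
counted without 15 minutes per day, minutes without any day, or weekly
minutes above 1440 × max(days, 1) — the "minutes exceed the minutes in
a day" check is operationalized with that formula, one day being
assumed when days is zero; and out-of-range vitals (height < 120 or
> 211 cm, weight < 20 or > 200 kg, completed age at the reference date
< 16 or > 115 years — missing height or weight is not an error).  The
any-problem flag is the OR of the mood, ADL, nutrition, ulcer and
therapy flags.  A record whose rule inputs are missing is excluded from
that rule's denominator rather than counted as error-free.

Pair-level rules: a diagnosis among {multiple sclerosis, quadriplegia,
cerebral palsy, schizophrenia} present at T1 and absent at T2 is a
reversal (records without the diagnosis at T1 are outside the
denominator); a block whose every item is identical at T1 and T2
(missing matching missing counts as identical) is a potential
carry-forward, computed for the 231 clinical quarterly variables, the
16 mood items and the 20 ADL items.  Diagnoses and the birthdate are
not part of the 231-item clinical block: the former have their own
longitudinal check, the latter is a fixed person attribute.

Sign-off lag is sign-off date minus reference date in calendar days,
categorized < 0 / 0–6 / 7–30 / > 30; the categories partition the
integers.

## Trend fits

Quarterly series are summarized by unweighted OLS of the quarterly
value on the quarter index with the sector's first observed quarter at
x = 1.  This anchoring was chosen by refitting the published quarterly
columns: with x starting at 1 the fitted intercepts and slopes
reproduce the printed summary rows across the published tables to
within about ±0.1 in the printed units, while a 0-based axis misses
several intercepts by 0.4–1.1.  The intercept is therefore the fitted
value one quarter-step before the first observation — close to the
first observed value for flat series.  Fits are unweighted; the handful
of published columns that refit slightly worse (two diagnosis-reversal
and two carry-forward columns, off by 0.2–0.7) are consistent with
those tables having been fitted on a different denominator or weighting
that the source does not state.  Note one sign quirk in the fixtures:
the published pain–CPS trend rows carry positive intercepts although
the quarterly series is negative; the fixture preserves the printed
values, and the refit reports the signed value (≈ −0.21).

## Association statistics

Cronbach's α uses the standard variance decomposition with sample
variances (n−1) and listwise deletion; fewer than three complete rows
or a zero-variance total give a missing α (no imputation anywhere in
the pipeline).  The ADL α is computed on the recoded (8→4) items, i.e.
on the metric the scale sums.  Cramér's V is √(χ²/(n·(min(r,c)−1)))
without bias correction or continuity correction.  Convergent validity
tracks, per quarter and sector: Cramér's V of bowel continence ×
(CPS 3+), and Pearson r of ADL×CPS, Pain×CPS and ABS×CPS.
Cross-setting concordance is the R² of the least-squares line through
paired named statistics from the two sectors — here 3 α values, 15
scale–scale Pearson correlations among the six scale scores and 171
item–item Spearman correlations among 19 selected items (189
statistics); at least three shared finite statistics are required, and
two identical constant lists count as perfectly concordant.

## Synthetic cohort

The generator emulates the structure the audit assumes, not any real
extract.  Each person carries a six-trait latent vector (cognition,
function, mood, aggression, pain, continence impairment) drawn from a
multivariate normal with a configurable correlation matrix (positive
semi-definiteness is checked before sampling) plus sector severity
offsets; the default correlations place cognition–function at 0.75,
cognition–continence at 0.70, cognition–aggression at 0.50 and
cognition–pain at −0.30, which reproduces observed scale-level
associations of roughly r ≈ 0.55 (ADL×CPS), r ≈ −0.2 (Pain×CPS) and
V ≈ 0.35 (bowel×CPS 3+) after categorization attenuates them.  Items
are generated by thresholding a loading-weighted trait plus fresh
standard-normal noise at fixed cutpoints; the within-block loading for
the ADL, DRS and ABS blocks is solved at generation time by bisection
against the configured α target (defaults 0.92 / 0.74 / 0.76) on a
calibration sample whose trait variance and mean match the
drift-widened, offset-shifted panel.  Traits drift as a random walk
(σ = 0.10 per quarter) within a stay, so longer-staying LTC residents
show slightly higher internal consistency — the direction the published
ADL α values also show.

Sector volume follows a steady-state queue: each quarter a fixed number
of records is emitted, a fraction `admission_share` of persons turns
over, and survivors are reassessed quarterly (every fourth reassessment
is an annual).  Turnover is simultaneously the admission share, so the
preset contrast (CCC 0.45, LTC 0.09) yields the published qualitative
pattern: admission share near one half versus under ten percent, and
about 2 versus 6 assessments per person over a 12-quarter window.
Persons entering at the window start are treated as mid-stay (their
first in-window record is a reassessment), which keeps the admission
share flat from the first quarter.  Sign-off lags are drawn from
per-sector category distributions matched to the published overall
rows; diagnoses are person-level constants (prevalence 6% each);
heights are person-level constants and weights get ±1 kg assessment
noise; 1% of heights and weights are missing.  All generated records
are internally consistent by construction: intake codes exist exactly
when a feeding route does, ulcer counts accompany stages, therapy
minutes lie within [15, 60] per reported day, mood persistence is
coded only when a mood item is present.  A clean cohort therefore
audits to exactly zero on every logical-error rule — the property the
test suite pins — while the carry-forward indicators retain a natural
no-change baseline (mostly all-zero mood blocks), which is measured,
not assumed.

Error injection mutates clean records into exactly each rule's
triggering condition and logs every mutation (with original values) in
a truth table keyed 1:1 to the records.  Cross-sectional and
carry-forward injections draw an exact count of targets,
`round(rate·n)`, without replacement — the injected rate equals the
configured rate up to rounding, which keeps recovery comparisons sharp;
at most one cross-sectional error is planted per record, and records
touched by a block copy are left alone so the two injection kinds never
mask each other.  Carry-forward copies the previous record's current
values (the mood section carries its persistence item along, as a real
copier would); diagnosis reversals are sequential Bernoulli draws over
carrier transitions and are persistent — once cleared, the diagnosis
stays absent for the remainder of the stay.  Deterministic rules give
total recall: audited counts equal injected counts exactly for every
cross-sectional rule and every reversal, and every injected block copy
is detected; a copy can flip the adjacent pair's natural-identity
status in either direction, a rare side effect that stays within the
binomial tolerance of the rate comparisons.

## What the synthetic results do and do not show

Passing recovery tests show the detectors, aggregation and trend
machinery are correct and that the generator hits its configured
targets; they do not certify any real repository's error rates, nor do
they reproduce the published population values (those derive from an
undeposited extract of 1.37 million assessments).  Features of real
data the generator deliberately omits: true clinical stability beyond
slow latent drift (natural mood/ADL no-change rates are far below the
published 35–50%), mortality and discharge destinations, facility-level
quality variation, fiscal-quarter administrative artifacts, and any
case-mix (RUG-III) grouping — the RUG-III grouper and Case-Mix Index
are out of scope throughout.

## Problem sizes and determinism

Unit tests run on a 400-records/quarter, 6-quarter cohort; the
recovery and concordance checks run on 2,000 records/quarter over 20
quarters (40,000 records, ≈ 29,000 pairs), the scale at which a 3-SD
binomial band on a 0.5% rate is still informative.  The acceptance
script uses 1,200 records/quarter over 12 quarters, enough for the
correlation and α targets to recover within ±0.02.  Everything is
deterministic under the configured seed (seeds split hierarchically:
calibration, per-sector generation, injection); distinct seeds give
statistically exchangeable cohorts.
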