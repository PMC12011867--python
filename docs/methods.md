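# Methods

## Data model and cleaning

The package consumes spontaneous-report databases in the public FAERS ASCII
dialect: per quarter, `$`-delimited tables DEMO (one row per report version:
identifiers, receipt/event dates, demographics), DRUG (one row per drug
mention with a role code PS/SS/C/I and, via INDI, an indication PT), REAC
(one row per reported MedDRA preferred term), OUTC (outcome codes
DE/LT/HO/DS/OT), THER (therapy start dates) — plus a deleted-case list.
Upstream files carry no quoting; our writer escapes an embedded `$` as `\$`
(and `\` as `\\`) so arbitrary free text round-trips.  Files are decoded as
UTF-8 with a logged Latin-1 fallback, because historical quarters mix
encodings.  Partial dates (`YYYY`, `YYYYMM`) are kept with an explicit
precision marker and never coerced to a fabricated day; any computation
needing a day (onset intervals) treats them as missing.

Deduplication is the FDA two-step rule.  Step one groups DEMO rows by
CASEID and keeps the row maximizing `(FDA_DT, PRIMARYID)` lexicographically;
step two removes kept reports whose CASEID appears on any loaded quarter's
deletion list.  Deletion lists are pooled across quarters and applied after
cross-quarter deduplication.  The conservation identity
`kept + dropped_duplicates + dropped_deleted = input` is asserted at run
time.  Reports referenced in child tables but absent from DEMO cannot be
deduplicated (CASEID and FDA_DT live only in DEMO); they are excluded and
counted, never silently dropped.

## Cohort and term normalization

The cohort is defined declaratively: drug-name patterns (case-insensitive
exact token match by default — FAERS drug names are free text, and exact
matching keeps the cohort auditable; substring matching is opt-in), a role
set defaulting to `{PS}`, and an indication PT list applied at report level
(any drug row's indication qualifies the report).  Everything not in the
cohort is the comparator background, i.e. the whole cleaned database, the
convention disproportionality methods assume.  Reports on the target drug
with a non-qualifying indication therefore sit in the background.

PT normalization case-folds, collapses whitespace, applies a synonym table,
and passes unmapped terms through with a counted warning.  MedDRA itself is
licensed; the bundled dictionary (`data/meddra_synthetic.tsv`, ~78 PTs with
plausible SOC assignments) exists so the pipeline runs out of the box, and a
real PT→SOC extract can be supplied at run time in the same two-column
format.

## Counting convention

The counting unit is the deduplicated report.  Each distinct PT counts once
per report, and the `b`/`d` cells count report–PT pairs
(`b = Σ_cohort |PTs(report)| − a`), which keeps the 2×2 margins internally
consistent when reports carry several reactions.  Whether published counts
of this kind are PT occurrences or distinct reports is usually ambiguous;
report-level counting is this package's documented choice, and a brute-force
recount is part of the test suite.

## Estimators

All four estimators are closed forms on `(a, b, c, d)`; see the README
table.  Numerical choices:

* **Zero cells.**  No continuity correction (none is standard for these
  criteria, and the a ≥ 3 minimum gates every criterion anyway).  Tables
  with an empty cell carry an explicit `degenerate` marker, report infinite
  or undefined estimates, and have all flags forced false.
* **BCPNN priors.**  The canonical Bate (1998) hyperparameters
  α = β = 2, α₁ = β₁ = γ₁₁ = 1, with the joint prior total
  γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)) derived from the margins so the
  prior is centred on independence.  All six are configurable.  The signal
  statistic is IC−2SD = E(IC) − 2√V(IC); a credible-interval IC025 variant
  is deliberately not implemented.
* **Simplified MGPS.**  EBGM = aN/((a+c)(a+b)) with a Wald interval on the
  log scale.  This is *not* the DuMouchel gamma-Poisson mixture: there is
  no shrinkage fitting.  For a large background database the value is close
  to the relative reporting ratio, and EB05 ≥ 2 behaves as a conservative
  threshold; the class is named and labelled "simplified" to prevent
  confusion with full MGPS.
* **Criterion boundaries** follow the stated inequalities exactly: ROR/PRR
  CI lower ≥ 1, PRR ≥ 2 (inclusive) for the PRR criterion but PRR > 2
  (strict) for MHRA, EB05 ≥ 2 inclusive.
* **Ranking.**  Table inclusion requires the ROR criterion (the frequency
  table of the reference analysis satisfies it row by row); frequency
  ranking orders by (a desc, PT asc), strength ranking by (ROR desc, a
  desc, PT asc), so results are order-independent and deterministic.
  SOC-level scoring counts a report once per SOC and reuses the same
  estimators.

## Reconstructing 2×2 cells from published rows

Published signal tables print per-row statistics but not the cells.  Those
statistics over-determine the three unknowns `b, c, d`: the Wald CI fixes
`SE² = 1/a+1/b+1/c+1/d`; ROR and PRR jointly fix
`b = a(PRR−1)/(ROR−PRR)`; χ² or EB05 fixes the scale of `c`.
`reconstruct_from_stats` solves by least squares on the log scale, each
residual weighted by the printed rounding precision (±0.005 on a 2-decimal
value), then refines to integers by local search.  The reconstructed table
reproduces its inputs at printed precision and predicts the row's remaining
statistic.  Identifiability varies by row: for high-magnitude rows the
printed precision pins the cells essentially uniquely, whereas for rows
where all ratio statistics depend on `c` only through a near-degenerate
combination, the held-out statistic is identifiable to roughly 0.1%
relative — the package reports the precision-weighted point estimate and
the tests assert at the identifiable precision.

## Descriptive strata

Default bucket schemes: age <18 / 18–44 / 45–65 / 66–75 / >75 years
(left-closed, so ages 65 and 66 land as the labels read), weight <73 /
73–87 / 88–104 / >104 kg, onset <1 / 1–3 / 3–6 / 6–12 / >12 months with a
30-day month (3–6 months = [90, 180) days).  Unit conversions: decades×10,
months÷12, weeks÷52.1775, days÷365.25, hours÷8766; lbs×0.453592,
grams÷1000.  Onset is event date minus the earliest full-precision therapy
start among cohort-matching drug rows; negative spans and partial dates
are counted as missing.  A report with several outcome codes contributes
its most severe (death > life-threatening > disability > hospitalization >
other), so outcome percentages are of reports, not codes; all percentage
tables include an explicit unknown category and state their denominator.

## irAE regression

The outcome is immune-related-AE occurrence per cohort report.  Spontaneous
reports carry no structured irAE field; the default rule flags any reaction
PT beginning `immune-mediated`, and the list is fully configurable.
Off-label use likewise has no structured field and is operationalized as
presence of the PT "product use in unapproved indication".  Covariates are
dummy-coded with the reference levels of the conventional reporting layout:
age <65, weight <50 kg, off-label *yes* (an unusual reference direction,
preserved deliberately to match the published coding).  Rows with missing
age or weight are removed listwise and the loss is reported.

Fitting is plain maximum likelihood via IRLS: convergence when the largest
absolute coefficient change is below 1e-8 (max 100 iterations),
step-halving whenever a step would decrease the log-likelihood (making the
likelihood path non-decreasing, which the tests assert), Wald covariance
from the inverse observed information.  Rank-deficient designs abort naming
the aliased columns; diverging coefficients (|β| beyond 30, or beyond 15
with vanishing weights or at the iteration cap) abort with a separation
error naming the covariate — sparse strata in small cohorts genuinely
separate, and the pipeline records the diagnostic instead of reporting
infinite odds ratios.  The test suite cross-checks coefficients and
standard errors against an independent maximum-likelihood implementation
and verifies 95% Wald coverage over 200 simulation replicates.

## Synthetic data generator

The generator emulates the *structure* of spontaneous-report data with a
law simple enough to invert:

* Reports are i.i.d.; a report is a cohort report (target drug as primary
  suspect plus qualifying indication) with probability `cohort_fraction`
  (default 0.15), otherwise its primary suspect is drawn from a background
  drug vocabulary.
* Reactions: K ~ zero-truncated Poisson(3) draws with replacement from a
  weighted PT vocabulary, de-duplicated.  The inclusion probability of a PT
  with normalized weight w is exactly `E[1−(1−w)^K]`, which is what
  `expected_table` evaluates; draws-then-dedup was chosen over
  distinct-count sampling precisely so this closed form is exact.
* Planted (drug, PT, RR) pairs multiply that PT's weight by RR for reports
  whose primary suspect is that drug, before renormalization.  For rare
  PTs the realized reporting odds ratio is close to RR; configurations
  whose tilted weight would exceed 1 are rejected as infeasible, naming
  the pair.
* Duplicate chains (12% of cases by default) emit 2–3 versions per CASEID
  with earlier receipt dates and smaller PRIMARYIDs, occasionally tying the
  date so the PRIMARYID tie-break is exercised; 2% of cases go on deletion
  lists.
* Demographics mirror the reporting pattern of checkpoint-inhibitor safety
  data in gynaecologic oncology: all-female cohort, age ~ Normal(58, 13)
  years (8% missing, some rows expressed in months or decades), weight
  log-normal with median 62 kg and CV ≈ 0.32 (35% missing; some rows in
  lbs), country and reporter-occupation mixes dominated by Japan/US and
  physicians, outcome mix other 52.8% / hospitalization 27.0% / death
  10.25% / unknown 6.06% / life-threatening 2.77% / disability 1.12%.
* Onset is log-normal with median 130 days and σ_log = 0.6, which puts the
  modal documented bucket at 3–6 months (≈ 44% of documented onsets); 42%
  of reports lack onset documentation.

What the generator does **not** emulate: drug co-prescription correlation,
free-text drug-name noise, reporting trends over calendar time, duplicate
versions with discrepant content, and region-dependent coding practices.
Passing recovery tests therefore demonstrates correctness of the pipeline's
counting and estimation on cleanly structured data, not robustness to the
messiness of real FAERS extracts.

`GroundTruth` records the realized post-dedup cells of every planted pair
and per-case flags (duplicate chain, deletion, irAE, onset), and the tests
require exact equality between ground truth and a full pipeline recount.

## Problem sizes and tolerances used in the test suite

Deduplication is checked against a brute-force oracle on random databases
of up to 500 reports; contingency counting against a direct double loop on
≤50-report fixtures; χ² against the expected-counts Pearson statistic
(relative 1e-9); BCPNN against an arbitrary-precision symbolic evaluation
on 100 random tables (relative 1e-10); the CI geometric-mean identities at
relative 1e-9.  Signal recovery uses a 2,000-report database with one pair
planted at RR = 20 (top-ROR recovery, all criteria met) and 200 replicates
of a 5,000-report null database with 100 background PTs (ROR false-signal
rate ≤ 10%; observed ≈ 2.5%, consistent with a one-sided 2.5% Wald
criterion plus the a ≥ 3 gate).  Logistic recovery uses n = 5,000 (log-odds
within ±0.15) and 200 replicates of n = 1,200 for CI coverage.  These sizes
keep the full suite under half a minute while leaving every stochastic
assertion multiple standard errors of headroom.

## Known limitations

* The simplified EBGM is not a shrinkage estimator; for very small `a` it
  is less conservative than true MGPS EB05.
* The off-label and irAE definitions are PT-based proxies; both are
  configurable but unavoidably approximate.
* The comparator is the whole cleaned database; within-indication
  comparators (restricting the background to the same disease context) are
  expressible via a custom `CohortSpec` but are not the default.
* Percentages in descriptive tables are rounded to two decimals and may
  total 99.99–100.01.
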