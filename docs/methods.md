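# Methods

## Problem and model

Spontaneous-report databases record suspected adverse events (AEs)
without denominators: there is no count of patients exposed to a drug,
only reports. Disproportionality analysis therefore asks a
within-database question — is event *y* reported with drug *x* more
often than the database-wide reporting rates of *x* and *y* would
predict under independence? Every method here reduces a drug–event
pair to the 2×2 table (a, b, c, d): reports of the target drug with /
without the event versus all other drugs with / without it,
N = a + b + c + d.

The four statistics and their signal thresholds:

| method | estimate | interval | threshold |
|---|---|---|---|
| ROR | ad/bc | exp(ln ROR ± 1.96·SE), SE = √(1/a+1/b+1/c+1/d) | a ≥ 3 and lower bound > 1 |
| PRR | [a/(a+b)]/[c/(c+d)] | exp(ln PRR ± 1.96·SE), SE = √(1/a−1/(a+b)+1/c−1/(c+d)) | a ≥ 3 and lower bound > 1 |
| BCPNN | IC = log₂[aN/((a+b)(a+c))] | IC025 = E(IC) − 2√V(IC) | IC025 > 0 |
| EBGM | aN/((a+c)(a+b)) | exp(ln EBGM ± 1.96·√(1/a+1/b+1/c+1/d)) | EBGM05 > 2 |

The PRR is accompanied by a Pearson χ² statistic; the Yates-corrected
form N(|ad−bc| − N/2)²/((a+b)(c+d)(a+c)(b+d)) is the default
(conventional alongside PRR screening), floored at 0 when
|ad − bc| < N/2, with the uncorrected form available by config. Both
variants are cross-checked against `scipy.stats.chi2_contingency` in
the tests; the implementation itself is self-contained.

The BCPNN moments use the Dirichlet-prior form with hyperparameters
γ₁₁ = α₁ = β₁ = 1 and α = β = 2 (the standard symmetric defaults,
exposed in config), and γ derived as
γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)), which makes the prior expectation of
IC zero. IC025 is the two-standard-deviation bound E(IC) − 2√V(IC),
not a posterior quantile. Because the priors regularize the counts,
E(IC), V(IC) and IC025 remain finite at a = 0 even though the observed
IC does not.

The EBGM implemented here is the closed-form relative reporting ratio
aN/((a+c)(a+b)) with a log-scale Wald interval. A full MGPS
empirical-Bayes gamma-mixture fit (DuMouchel-style EM over the whole
drug–event matrix) is deliberately out of scope; the closed form is
what this pipeline reports and tests. Consequently IC equals
log₂(EBGM) exactly — a cross-method identity the property tests
exploit. Note that published IC columns produced by shrinkage
implementations are E(IC)-like and can deviate slightly from
log₂(EBGM); both `ic` and `e_ic` are therefore reported side by side.

Zero cells: no continuity corrections anywhere. An estimate whose
formula is undefined for a table is marked non-computable (NaN),
reported as `NA`, and its flag forced false; nothing is silently
dropped. Multiple-testing adjustment is intentionally absent — signal
screening in this tradition applies per-pair thresholds.

## Pipeline conventions

**Dialect.** FAERS quarterly ASCII: `$`-delimited, header row, no
quoting. Dates are kept as raw 4/6/8-digit strings plus a parsed date
set only for valid YYYYMMDD values; malformed date strings become
missing with a warning rather than failing the row. Rows are never
silently dropped: parsed + rejected counts are logged per file.

**Dedup.** One report version per CASEID survives: the maximum by
(FDA_DT, then PRIMARYID), compared on the integer value of the raw
strings so partial dates order deterministically, with missing FDA_DT
sorting lowest (a dated version always beats an undated one). Records
with no CASEID cannot be grouped and are kept. Deduplication runs
globally across loaded quarters, then the union of deleted-case lists
is applied, then child-table rows of removed versions are dropped.
The kept set is permutation-invariant and idempotent (property-tested).

**Cohort.** A report qualifies when ≥ 1 drug row has a qualifying role
(default: PS only) and a drug name or active ingredient containing the
keyword as a case-insensitive substring. Age bins are half-open
[0,18), [18,45), [45,65), [65,75), [75,∞) so every age maps to exactly
one bin; published bin edges that nominally overlap force some such
convention, and half-open intervals are the standard one. Report year
comes from FDA_DT of the kept version. Serious outcomes count reports
with multiplicity across distinct codes (a report can be both
hospitalized and fatal), so outcome percentages need not sum to 100.
Time to onset is event date minus the earliest therapy start among
target-drug rows, requiring full dates on both sides; negative
differences (therapy after event) are dropped with a warning, and the
computable fraction is logged. Constituent ratios are percentages
rounded half-up to 2 decimals; with k categories the rounded
percentages of a partition can drift from 100 by up to 0.005·k.

**Counting unit.** The contingency unit is the distinct
(report, event) pair: a PT repeated on one report counts once, and at
SOC level a report counts once per distinct SOC. Margins b and d are
unit totals, which keeps N constant across events at a level — the
property that makes per-event tables comparable. The report-based
comparator (`unit="reports"`), where b and d count reports, is
available for sensitivity analysis; it is also the scale on which the
generator's ground truth is exact (below). PTs missing from the
terminology map fall into an explicit `UNMAPPED` SOC bucket rather
than vanishing. MedDRA is licensed, so the PT→SOC map is always an
external two-column TSV (or the synthetic fixture).

## Synthetic corpus generator

The generator emulates the structure of FAERS that the pipeline must
survive, with a ground truth that recovery tests can hold it to. Per
case: one PS drug from a Zipf-weighted catalogue plus
Poisson-distributed extra drugs in SS/C roles; each PT enters the
report independently with a small background probability π_p (Zipf
weights scaled to a mean of ~2 PTs per report); reports drawn empty
are redrawn so every report lists ≥ 1 reaction. A signal spec
(drug, PT, λ) replaces π with λπ/(1 − π + λπ) on reports whose PS drug
matches — a multiplicative odds injection, so the report-level odds
ratio between that drug's cohort and all other reports equals λ
exactly, and conditioning on ≥ 1 reaction cancels from the ratio.
The pairs-based ROR converges to λ only up to a finite-sample
distortion that grows with π and with the cohort's share of all units;
the unbiasedness test therefore measures λ-recovery with the
report-based comparator, while threshold-recovery tests use the
default pairs units.

Structural artefacts: a configurable fraction of cases (default 10%)
is emitted twice — same CASEID and clinical fields, fresh PRIMARYID,
same or later FDA_DT — so dedup correctness is exactly checkable
(kept reports must equal distinct cases minus deletions); a fraction
of cases (default 2%) goes on the deleted list; event dates are
missing (2%) or partial (5%); drug names vary in casing/punctuation to
exercise substring matching. Demographic mixtures default to a
composition typical of a large psychotropic-drug cohort: 56.5% female,
ages ~N(46, 20²) with 28% missing, consumer-dominant reporters,
US-majority countries, and report volume ramping linearly 2004→2023.
All draws flow through one `numpy` generator seeded from the config,
so a (config, seed) pair maps to byte-identical output files.

What the generator does **not** emulate: correlated co-reporting
(indication-driven drug–event dependence, polypharmacy structure),
free-text drug-name noise beyond casing, reporting-rate drift within a
pair over time, and duplicated cases with *divergent* clinical
content. Passing recovery tests therefore show the pipeline machinery
is correct under the stated mechanism, not that real-database signals
are unconfounded.

## Study conditions used by tests and the acceptance script

Simulation experiments use corpora of 6,000 cases, 20 drugs and 40
PTs, with the target drug at Zipf rank 6 (~4.6% of reports) so the
cohort neither starves the signal cells nor dominates the comparator;
injected pairs (λ = 10 and λ = 15 on mid-tail PTs) have expected
cohort counts of roughly 35–70, comfortably in the regime the
thresholds are meant to detect. Recovery is evaluated over 20 seeds.
Null calibration simulates 2,500 fixed-margin null pairs
(hypergeometric a; N = 100,000, cohort margin 2,000, event margins
drawn so E[a] spans 3–60) and measures how often the ROR criterion
fires; the acceptance bound is 2.5% plus three Monte-Carlo standard
errors. Measured rates sit slightly above 2.5% on average because
Wald intervals on a log odds ratio are mildly anticonservative at
small expected counts — a property of the screening criterion itself,
visible here precisely because the null is exact.

Formula exactness is established against an independently coded
oracle (a literal step-by-step transcription of the published
formulas, sharing no code with the package) on 1,000 random tables
with cells up to 4,000, at 10⁻¹⁰ relative tolerance; observed
agreement is at machine precision (~10⁻¹⁵).

## Numerical and design choices

- Statistics are computed in double precision from the exact integer
  cells; report output rounds to 2 decimals, `NA` for non-computable.
- Ranking is a stable descending sort with ties broken by
  (case count desc, label asc); NaN EBGM sorts last.
- Age units convert to years by YR×1, DEC×10, MON÷12, WK÷52.1775,
  DY÷365.25, HR÷8766; an age with no unit is taken as years with a
  warning.
- Reporter, outcome and country codes pass through verbatim with a
  small display map; country harmonization ("US" vs "United States")
  is left to the user's mapping because source conventions vary.
- The deleted-case list is applied after dedup, as the quarterly
  packages intend; a deleted CASEID never seen in the corpus is
  ignored with a debug note.

## Known limitations

- The closed-form EBGM lacks the shrinkage of a fitted gamma mixture:
  for very small a its interval is wide rather than shrunk toward 1,
  and EBGM05 > 2 behaves more like a Wald criterion than an EB05 one.
- Pairs-based margins make every event's table share one N but bias
  the ROR toward 1 relative to the report-level odds ratio when the
  cohort's unit share is large; the `unit` switch exposes the
  trade-off instead of hiding it.
- No stratification (age/sex/year) and no fuzzy duplicate detection
  (the same patient under different CASEIDs); both are out of scope.
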