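# Methods

## Data model and deduplication

The pipeline consumes quarterly bundles in the FAERS ASCII layout:
"$"-delimited DEMO, DRUG, REAC, OUTC, THER and INDI tables keyed by
PRIMARYID (a report version) with CASEID identifying the underlying safety
case, plus an optional deletion list of CASEIDs (present in quarters from
2019Q1 onward).  Files are decoded as latin-1 with replacement, since real
extracts are not clean UTF-8.  Rows with the wrong column count are dropped
and tallied per table, never fatal; a missing DEMO/DRUG/REAC table aborts
with the table name.

Reports from all quarters are pooled before deduplication because
duplicate report versions span quarters.  The FDA-recommended rule is
applied per CASEID: keep the report with the most recent FDA_DT; on ties,
the higher PRIMARYID.  Valid `YYYYMMDD` strings are compared as text
(lexicographic equals chronological); an empty or truncated FDA_DT is
treated as minimal so an informative date always wins.  Deletion lists are
pooled across quarters and applied **after** dedup, matching the usual
description of the procedure ("following data deduplication, reports were
systematically excluded"); unknown CASEIDs on a list are counted, not
errors.  Dedup is idempotent and order-invariant, and conservation
(`reports = cases + duplicates removed`) is asserted in tests.

Dates are kept as raw digit strings plus a `(year, month, day)` triple in
which components may be absent; nothing is imputed.

## Cohorts and characteristics

A cohort is every deduplicated, deletion-filtered case in which the target
drug appears with role code PS (primary suspect).  Drug matching is
case-insensitive substring matching over DRUGNAME and PROD_AI with a
user-supplied synonym list, since FAERS names are free text; an `exact`
mode is available.  Events are (caseid, PT) pairs with repeated PTs within
a case collapsed — the event-level counting unit used throughout.

The characteristics table partitions the cohort on sex, age band (<18,
18–64, ≥65), weight band (≤50, 51–100, >100 kg), reporter occupation,
report year (from the surviving report's FDA_DT), time-to-onset band
(≤30, 31–180, 181–360, ≥361 days) and daily-dose band (≤20, 21–50, 51–100,
101–200, ≥201 mg/day), each with a "Not specified" category so counts
always sum to the cohort size.  Percentages are 100·count/total rounded
half-up to two decimals, the convention of published characteristics
tables.  Outcome counts are the exception to the partition: a case is
counted under every outcome code it carries, because published outcome
rows overlap; a `worst_outcome_only` mode (DE > LT > HO > DS > CA > RI >
OT) restores a partition when wanted.  Age units (YR/DEC/MON/WK/DY/HR) are
converted to years before banding; doses parse from free text such as
`"25 MG, BID"` (amount × unit × frequency), with anything unparseable
landing in "Not specified".

Time to onset is EVENT_DT − START_DT in whole days, using the earliest
fully-specified start date among the case's primary-suspect therapy rows.
Cases are excluded, with reason codes, when either date is missing, when a
present date is imprecise (day or month truncated), or when the onset is
not strictly after initiation (EVENT_DT ≤ START_DT).  The strict reading
(`tto_days ≥ 1`) is the default; `strict=False` admits 0-day onsets.
Conservation (`cohort = records + exclusions`) is asserted in tests.

## Disproportionality statistics

All four statistics are computed from the per-term 2×2 table built against
a background of every deduplicated case whose primary-suspect drug is not
the target (the full-database comparator; when two drugs are compared,
each keeps the full remainder as background unless
`exclude_comparator_from_background` is set).

The formulas are implemented exactly as stated in the README.  Numerical
notes:

- Comparisons and flags are computed unrounded; rounding to two decimals
  happens only in output formatting.
- Zero cells leave ROR, PRR and EBGM undefined (NaN) and the method flag
  false.  No Haldane/Yates-style 0.5 correction is applied: the a ≥ 3
  count floors in the ROR and MHRA rules mean a correction could never
  rescue a signal, so encoding "undefined" honestly is preferable.
- The BCPNN branch uses the closed-form posterior E(IC)/V(IC) with the
  standard priors (α₁ = β₁ = 1, α = β = 2, γ₁₁ = 1), not a Monte-Carlo
  posterior; it is defined for every non-negative table, including a = 0,
  where shrinkage yields a finite negative IC025.
- The MGPS branch is deliberately the closed-form relative reporting ratio
  `EBGM = aN/[(a+c)(a+b)]` with a log-normal lower bound, **not** the
  DuMouchel empirical-Bayes gamma–Poisson mixture.  This matches the
  closed-form presentation common in the applied pharmacovigilance
  literature this package follows; users needing the mixture-model EBGM
  should treat this column as the unshrunk relative reporting ratio.  One
  consequence worth knowing: when the target cohort is a large fraction of
  N, EBGM sits systematically below ROR/PRR, and EBGM05 > 2 becomes the
  binding constraint of the consensus rule.
- A vectorised implementation of all flags (`vectorized_consensus`) backs
  the replicate studies; a property test pins it bit-for-bit to the scalar
  path, including zero-cell handling.

Both PT- and SOC-level tables are supported; SOC rollup maps each PT event
to exactly one SOC through a user-supplied two-column dictionary (real
MedDRA is licensed and is not shipped), with unknown PTs routed to an
`UNMAPPED` class so event totals are conserved.  SOC-level counting
collapses a case's multiple PTs within one SOC to a single event by
default.

## Sex-stratified analysis

Within one cohort, each PT reported by both sexes gets a female/male 2×2
table over the cohort's event totals (cases of unspecified sex are
excluded from both margins).  The modified ROR reuses the drug-event
formulas; the p-value is the upper tail of the Pearson χ² at 1 df, without
continuity correction (Yates available via flag), without a minimum-count
floor, and without multiple-testing correction by default — published
sex-difference tables in this field report raw p-values at nominal
thresholds, and several of their rows have cells of 1–2.  Direction is F
if ROR > 1 and p < 0.05, M if ROR < 1 and p < 0.05, else none.  Row-swap
antisymmetry (ROR → 1/ROR, p preserved) is tested exactly.  Volcano
coordinates are (log₂ ROR, −log₁₀ p) per PT with undefined entries dropped
and counted.

## Synthetic data generator

The generator emulates the *structure* of spontaneous-report extracts, not
any particular drug's term frequencies.  Each case draws: a primary-suspect
drug (target or one of 40 interchangeable background drugs); a sex from a
0.65/0.28/0.07 female/male/unspecified mix (the margin typical of SNRI
cohorts); an event count k from a zero-truncated Poisson with λ = 2.8
(mean ≈ 3.0 distinct events per case, matching the ~3.1 events-per-case
ratio seen in such cohorts); and k preferred terms drawn with replacement
from a 60-term power-law catalog (rate ∝ 1/(i+4)) and collapsed to the
distinct set.  Planted disproportionality multiplies a PT's weight in the
target arm; sex effects multiply it for female target-arm cases.  Because
weights renormalize, planting one term slightly *dilutes* every other
term's share in that arm — expected RORs of unplanted terms drift a few
percent below 1, and a planted ×m term's expected ROR is somewhat below m
for common terms (the rare-term limit recovers m).  The closed-form
expectation `expected_table` integrates the distinct-collapse over the k
distribution and the sex mix and serves as the recovery oracle.

Realism features: FDA_DT/EVENT_DT/START_DT are sampled around each
quarter; dates go missing at configurable rates and present dates are
truncated to month or year at a configurable imprecision rate; age, weight
and dose have independent missingness, doses render in FAERS free-text
styles ("50 MG, QD", "UNK"); duplicates re-emit a case with a higher
PRIMARYID and later FDA_DT into the last quarter; deletion lists are
written only to quarters labelled ≥ 2019Q1.  Identical configs produce
byte-identical bundles.

What the generator does **not** emulate: drug-name typos and synonyms,
real MedDRA term frequencies or hierarchies, correlated event co-reporting
(terms are conditionally independent given the case), polypharmacy with
informative concomitants, or reporting trends over time.  Passing the
planted-recovery suites therefore shows the *statistical machinery* is
correct and calibrated under a known model — not that any particular
real-data signal is causal, nor that free-text drug matching will be
complete on real extracts.

A count-level fast path (`simulate_counts`) draws the same model directly
as per-PT contingency counts, skipping file I/O; the replicate studies in
`pvsignal.studies` use it so that 200-replicate operating-characteristic
runs finish in about a minute.  The file path is exercised end-to-end at
5,000 cases.

## Study sizes and seeds

The validation studies use 2,000 target / 50,000 background cases, six
planted PTs at multipliers {2, 5, 10} (two each), 200 replicates for
detection and sex-analysis calibration, and 50 replicates (60 terms each)
for null false-positive rates.  At these sizes every planted PT has
expected a ≥ 20.  Multiplier 2 sits below the consensus rule's detection
boundary (PRR ≥ 2 and EBGM05 > 2 are marginal at true ratio ≈ 2), so its
detection rate is reported but no threshold is asserted; m ≥ 5 must be
detected in ≥ 95% of replicates.  All replicate seeds spawn from a single
`numpy.random.SeedSequence`, so every reported number is reproducible from
one integer seed.

## Design choices on genuinely open points

- Deletion lists applied after dedup (flag-free; the alternative ordering
  changes nothing when deleted CASEIDs are deleted wholesale).
- Multi-axial PTs: a PT maps to exactly one SOC; the dictionary loader
  rejects conflicting duplicates rather than guessing a primary axis.
- SOC-level counting: events (distinct PT set rolled up, then collapsed
  per case-SOC) by default; per-case counting is what the rollup of
  `unique_events` yields after collapsing.
- Sex analysis direction uses the χ² p-value rule; the CI lower bound is
  also emitted so the alternative "CI excludes 1" reading can be applied
  downstream.
- Output tables are sorted (consensus desc, a desc, term asc) and floats
  printed with `%.6g`, making reruns byte-identical for diffing.

## Known limitations

- The closed-form EBGM is not shrunk; rare terms with a single-digit `a`
  can show large EBGM values that a gamma–Poisson fit would pull toward 1
  (the a ≥ 3 floors and the consensus rule mitigate, but do not remove,
  this).
- The Wald ROR interval is asymptotic; for cells of 1–2 its coverage is
  approximate, which is the standard caveat for published sex-difference
  tables with tiny cells.
- Free-text drug matching is substring-based; it will not catch
  misspellings and may over-match short synonyms.
- The ingest path materialises one Python record per report; it is
  comfortable at hundreds of thousands of reports but is not tuned for the
  full multi-gigabyte historical database.
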