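# Methods

This note documents the models, conventions and numerical choices behind
`comorbarm`, in the order the pipeline runs.

## Cohort construction

Diagnoses are normalized by stripping whitespace and dots, uppercasing, and
truncating to the first three characters; codes outside ICD-10 chapters A–N
(pregnancy, perinatal, congenital, symptom, external-cause and administrative
codes) are discarded. Visits are aggregated per patient per calendar year and
each code is kept at its earliest year only. All time arithmetic is in whole
years; no finer resolution exists anywhere in the package.

The index year is the first year containing an E11 code, moved earlier when a
free-text note carries a stem-scoped onset year that precedes it. The
extractor splits a note into clauses at `; . ! ?` and accepts a 4-digit year
(1900–2099) only if it follows one of the keyword stems `diabetes`, `T2DM`,
`E11` inside the same clause; the earliest such year across a patient's notes
is used. The real notes behind the motivating study design are not available,
so the supported date dialects are a package convention, matched exactly by
the synthetic note templates.

Exclusion filters run in a fixed order — (1) confirmed E11 index, (2) age at
index ≤ 100, (3) at least one visit in the five years before the index year
(predating the first recorded E11) — and a funnel records patients remaining
after each. Funnel shares are percentages **truncated** (not rounded) to one
decimal; truncation never overstates the retained share.

Timeframe classes partition integer offsets (first-occurrence year − index
year): `n5-n1` = −5…−1, `0-4`, `5-9`, `10-` = 10+. Offsets below −5 are
dropped entirely rather than pooled, since the pre-index class is defined as
exactly five years. An offset of 0 (a comorbidity recorded in the index
calendar year) is post-diagnosis. Each patient emits one transaction per
*observable* class — the class's calendar window must overlap
`[first visit year, min(death year, last visit year)]` — and empty
transactions are retained so that per-class transaction counts equal
per-timeframe patient denominators (local support then reads directly as "x%
of observable patients"). Whether patients without new in-scope diagnoses in a
timeframe belong in that denominator is not externally fixed; including them
is this package's convention and is what makes local support a prevalence.

## Rule mining

Frequent itemsets are mined per class partition with an in-house FP-growth
(prefix tree, conditional pattern bases, no candidate generation); its output
is defined to equal exhaustive enumeration and is tested against a brute-force
subset counter. The per-class minimum count is `ceil(threshold ×
class_size)`, which makes the fractional criterion exact at the boundary.

Every surviving antecedent is scored against all classes. Lift entries for
classes where the antecedent is absent are 0 and *included* in the
exclusiveness denominator — absence is informative when comparing relative
strength across classes. Two algebraic identities are enforced to 1e-12:
`lift = local_support / support(A)` and `lift = confidence / support(c)`;
exclusiveness values sum to 1 (±1e-9) per antecedent. Confidence is computed
and reported but never used for pruning. Rule tables are ranked by lift
descending with ties broken by antecedent code ascending (a determinism
convention) and truncated to exactly the top 15 — no tie expansion, unlike
the network node selection. Threshold-grid counts are of post-size-filter
rules (single-morbidity antecedents) per class.

## Statistics

Gender odds ratios are crude (unadjusted), male vs. female with females as
reference: `OR = (m1·f0)/(m0·f1)`, Wald CI
`exp(ln OR ± 1.96·√(1/m1+1/m0+1/f1+1/f0))`. Degenerate tables are flagged
rather than continuity-corrected: a zero numerator reports 0.00 [0.00–0.00],
a zero denominator reports an infinite OR, an empty sex margin reports
`empty_margin`. No Haldane–Anscombe correction is applied because a flag is
more honest than a fake number; no multiple-testing correction is applied.

The adjusted temporal ratio of a condition is its per-class prevalence divided
by the mean of its four prevalences. Only the range [0, 4], the sum-to-4
identity and the >1/<1 reading are externally constrained; prevalence over
cross-timeframe mean is the unique linear statistic meeting all three with
four classes, and is documented here as this package's formula.

Per-timeframe descriptives use age at the index year (mean, sample SD, median,
interpolated Q1/Q3 and their width). The death percentage counts deaths
occurring during or before the class's calendar window among that class's
observable patients (any recorded death, for the open-ended last class); the
denominator definition is a package convention, stated because no external
one exists.

## Co-occurrence networks

Node occurrence counts class transactions (patients, not visits) containing
the code; an edge weight is the number of patients carrying both codes in the
class — the within-class support of the pair, which is verified against the
miner. Degree centrality is the raw count of distinct neighbours. Node
selection takes the top 15 by degree (secondary: occurrence, tertiary: code)
and *extends the cut through all degree ties* at rank 15. Exports (GEXF,
GraphML, edge CSV) carry occurrence, degree, the occurrence share of the
class denominator, and raw edge weights; layout and colour binning are left
to the viewer (Gephi).

## The synthetic-data generator

The generator emulates the structure of a 2007–2021 administrative hospital
extract: ~25,000 patients, 46% male, age at index ~N(63.2, 13.9²) clipped to
[18, 99], index years uniform over 2008–2021, free-text notes for 77% of
patients of which 8% carry an earlier onset year, yearly attrition 0.06 and
death hazard 0.02 after the index year. Planted violator groups (2% without
any E11 record, 1% aged over 100, 5% without a pre-index visit) exercise the
cohort funnel with exactly known counts. These defaults are the package's
study conditions; they are not tuned per run.

Each (patient, condition) pair first occurs in exactly one timeframe class or
never: one categorical draw assigns class *m* with probability
`p_m = base_rate × 5 × enrichment_m × gender_factor × bundle_factor`
(configurations are validated so these sum to ≤ 1; the factor 5 converts an
annual base rate to a nominal 5-year class probability). Observable classes
form a prefix of the four — a later class requires surviving attrition, death
and the window end to its start — so the rate of a condition among class-*m*
transactions is exactly `p_m`, a flat enrichment vector implies lift exactly
1 everywhere, and implied lifts and gender odds ratios have closed forms
(`implied_lift`, `implied_gender_or`). Optional pairwise "bundles" give a
latent carrier subpopulation a common rate multiplier on two codes, planting
co-occurrence for the network stage while keeping marginals analytic.
Occurrences assigned to a class the patient never becomes observable in are
never recorded, mirroring right-censoring.

Randomness comes from per-patient sub-streams keyed by (seed, patient index),
so output is bit-reproducible and independent of generation order. Duplicate
later-year echoes of each diagnosis, raw-code variants (suffixes, dots,
lowercase) and out-of-scope filler codes exercise deduplication,
normalization and chapter filtering without perturbing the mined itemsets.

What the generator does *not* emulate: realistic clinical note language,
primary-care underrepresentation, correlated condition onsets beyond the
planted bundles, within-year timing, or the marginal ICD frequency spectrum
of a real hospital. Passing recovery tests therefore demonstrate correctness
of the estimators under this generative family, not clinical validity on real
records.

## Recovery benchmarks and calibration

The recovery benchmark plants 100 synthetic conditions (log-uniform base
rates 0.004–0.015, log-uniform gender rate ratios 0.5–2, one enriched class
per condition with multiplier 1.5–3) in a 25,000-patient cohort. Mined lifts
are compared against 99% Monte-Carlo intervals of the implied lift: the
interval simulation reproduces the count-level generative process exactly
(multinomial observability strata, one categorical first-occurrence draw per
patient), capturing the negative coupling between classes. Checks are
restricted to (condition, class) pairs with ≥ 300 expected occurrences, where
the normal-range reasoning behind the interval is sound, and at least 97% of
pairs must fall inside their 99% intervals. Gender ORs are evaluated in each
condition's enriched class — where the planted effect lives and counts are
adequate — and their Wald 95% CIs must cover the implied OR for at least 93%
of conditions; replicated simulation puts the expected coverage at 95.0%
(SD 1.8 over 10 generation seeds), so this bound holds with margin in
expectation while remaining a genuinely stochastic check. Wald calibration is
verified separately: over 2,000 simulated 2×2 tables at a fixed true OR of
1.6 with 600 patients per arm, empirical coverage must lie in 93–97%.

Problem sizes in the default test-and-acceptance runs (2,000-patient demo,
25,000-patient benchmark, 20,000 Monte-Carlo replicates per interval, 2,000
calibration tables) were chosen so the full battery completes in well under a
minute each while keeping every binomial standard error small relative to the
asserted tolerances.

## Known limitations

- The exclusiveness denominator includes only classes present in the
  transaction database; a class with zero transactions is skipped with a
  warning rather than entering as lift 0.
- Implied gender ORs are undefined (infinite) for conditions absent in one
  sex; the estimator reports the matching degenerate flag instead of a number.
- The adjusted ratio requires all four classes to be populated; studies with
  shorter windows need a different normalization.
- Attrition and death act only after the index year; pre-index presence is
  guaranteed by construction for eligible patients, so the generator cannot
  represent patients whose pre-index observation is itself censored.
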