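# Methods

## Counting model

The engine operates on OMOP CDM v5 extracts: clinical events are taken
from `condition_occurrence`, `drug_exposure` and `procedure_occurrence`
(concept-id columns `condition_concept_id`, `drug_concept_id`,
`procedure_concept_id`; date columns `condition_start_date`,
`drug_exposure_start_date`, `procedure_date`, overridable), demographics
from the `person` table's `gender_concept_id`, `race_concept_id` and
`ethnicity_concept_id`. Person ids are assumed to uniquely identify
patients. Events with concept id 0 — OMOP's "no matching concept"
sentinel — are dropped at read time and tallied, since unmapped codes
would otherwise pollute the prevalence tables with a meaningless
pseudo-concept; datetime stamps are truncated to dates.

For one dataset window (inclusive on both endpoints; `None` = lifetime),
each patient's record is reduced to a *set* of concept ids: all in-window
clinical concepts, plus the person's non-zero demographic concept ids. A
patient enters the dataset — and the denominator `N_P` — only if at
least one clinical event falls in the window; demographics alone never
qualify a patient, but once a patient is included their demographic
concepts are counted singly and in pairs like any other concept (so
gender × condition pairs exist in the release).

Single counts `N_C` and pair counts `N_{C1,C2}` are unique-patient
counts over these sets. Pairs are unordered, stored once in ascending-id
order; self-pairs are not emitted (a self-pair would just repeat the
single count). Counting deliberately ignores temporal structure within a
patient: any two concepts anywhere in the window co-occur. Pair counting
enumerates `itertools.combinations` over each patient's sorted set —
exact and fast at the cohort sizes this package targets; the test suite
keeps an independent brute-force double loop as the counting oracle.

Extraneous domains that leak into the three event tables (Device,
Measurement, Observation, …) are kept without special-casing: they do not
affect the counts of conditions, drugs, procedures or demographics.

## Disclosure protection

The release pipeline is fixed, in this order:

1. **Iatrogenic-code removal.** A two-column (vocabulary, code) list is
   resolved against the concept dictionary; matching concepts are removed
   from the single table and any pair containing one is removed from the
   pair table. Removal happens before any release artifact is produced.
2. **Rare-count exclusion.** Items with true count ≤ 10 (threshold
   configurable, `min_count_threshold`) are excluded. The boundary is
   strict: a count of exactly 10 is excluded, 11 is retained.
3. **Poisson randomization.** Every remaining count is replaced by one
   draw from a Poisson distribution with mean λ equal to the true count.
   Exclusion precedes randomization, so λ > threshold always; randomized
   values of any non-negative size — including values ≤ 10 — are
   retained, because re-filtering after randomization would bias the
   released count distribution. Singles and pairs are randomized
   independently, which is why a released relative frequency can exceed 1.

Each draw is keyed by `SeedSequence(master_seed, crc32(dataset_id),
concept key)`, making results deterministic, order-independent, and
independent across datasets and annual windows. The Poisson's relative
perturbation shrinks as λ grows (SD/mean = 1/√λ), so rare concepts — the
re-identification risk — are perturbed proportionally most.

**Impact validation.** `randomization_impact` applies a one-degree-of-
freedom Pearson goodness-of-fit statistic `(O − E)²/E` (O = randomized,
E = true count, no continuity correction) against the χ²(1) critical
value at α (default 0.05). This is the simplest test consistent with a
"chi-squared analysis on the counts", and for calibrated Poisson noise
the flagged fraction converges to α as λ grows (normal limit of the
Poisson); the acceptance script demonstrates ≈5% on 50,000 simulated
counts with λ log-uniform on [50, 10⁵]. Whether the test is viewed as
one- or two-sided does not arise: the statistic is quadratic.

## Annual stability statistics

For each calendar year fully covered by data (the `full_years` list is
explicit configuration, never inferred from the events, since partial
coverage cannot be detected from the rows themselves), the engine counts
that year as its own window with its own annual `N_P`. The released
*mean* annual rate is computed over **randomized** annual counts — each
year randomized with a year-specific key — while the *standard
deviation* is computed over **true** annual rates, preserving an
unbiased stability signal. A concept absent in a year contributes rate
0; a year with no clinical events at all has an undefined annual `N_P`
and is skipped with a log message. The SD convention is population SD
(ddof = 0) by default, configurable to sample SD; the released files do
not distinguish the two, so the choice is documented rather than
encoded.

## Association measures

All three measures are functions of `(N12, N1, N2, N_P)` and are served
from released (post-privacy) counts; a true-count mode exists for
internal validation only.

- **Chi-square**: Pearson on the 2×2 table
  `[[N12, N1−N12], [N2−N12, N_P−N1−N2+N12]]`, df 1, no Yates correction
  (expected cells in released data are large). Randomized counts can
  make a cell negative; that raises a structured inconsistency error
  naming the cell rather than returning a bogus statistic.
- **Relative frequency** `FR(C1|C2) = N12/N2`. In ranked queries the
  conditioning is `FR(anchor | partner)` — among patients with the
  partner concept, the fraction also observed with the anchor — which is
  the ordering that surfaces specific partners instead of merely
  prevalent ones.
- **Log ratio** `LR = ln(N12·N_P/(N1·N2))`; `N1·N2/N_P` is the pair
  count expected under independence and is reported alongside. A zero
  pair count is signalled as undefined rather than returned as −∞.

Ranked queries break ties by ascending concept id, so output is
deterministic. No multiple-testing correction is applied across pairs;
association is not causation, and the documentation of query results
says so rather than pretending otherwise.

## Synthetic cohorts

The generator draws per-patient concept sets from a catalog of
(concept_id, domain, marginal prevalence) entries. Concepts are mutually
independent except for explicitly listed **disjoint** pairs, for which
the joint cell `p11` is solved from the 2×2 odds-ratio identity
`OR = p11·p00/(p10·p01)` (quadratic; the root inside the Fréchet bounds
`[max(0, p1+p2−1), min(p1,p2)]`). Any positive odds ratio is feasible
for marginals strictly inside (0,1); imposing dependence on a degenerate
marginal (0 or 1) is rejected with an error naming the pair. Disjoint
pairs suffice to test the sign and magnitude behaviour of the
association measures; overlapping dependence structures are rejected
rather than approximated.

Each positive patient-concept emits `1 + Poisson(events_per_positive − 1)`
duplicate event rows (default mean 1.5 rows), dated uniformly over the
year range — exercising the deduplication the counting stage must
perform, with no within-patient temporal structure (the counting model
ignores temporal relations anyway). Demographics are categorical draws
per group with the unassigned mass mapping to concept id 0; the default
mix (55% female / 44% male; substantial unmapped race/ethnicity mass) is
shaped like a large US academic medical center, where unmapped
race/ethnicity is the norm rather than the exception.

What passing tests on synthetic cohorts shows: the counting, privacy and
association machinery is exact and calibrated under known marginals and
dependence. What it does not show: behaviour under real EHR phenomena —
visit structure, coding drift (e.g. ICD-9→ICD-10 transitions), duplicate
patient registrations, care-process-driven detection bias. Those affect
the interpretation of EHR prevalence, not the correctness of the
arithmetic.

Default study conditions used by the tests: 10,000 patients for
parameter-recovery checks (marginals and odds ratios recovered within 4
standard errors), 200-patient random cohorts for oracle equivalence,
50,000 simulated counts for the randomization calibration. These sizes
give Monte-Carlo error well inside the asserted tolerances while keeping
the suite fast.

## Release files and query service

A release is a directory of tab-delimited files per dataset — single
counts `(concept_id, count, prevalence)`, pair counts `(concept_id_1,
concept_id_2, count, prevalence)`, and the deviation companions with
`(mean, sd)` — plus one shared `concepts.txt` with the six OMOP concept
columns, and a small `metadata.json` carrying dataset windows and
patient counts. All frequencies are relative to 1.0. Files carry a
header row by default (self-describing; `header=False` gives the strict
positional layout), frequencies render at 6 decimals (full precision
optional), and row order is canonical, so write → read → write is a
byte-identical round trip. Pair rows found out of canonical order on
read are normalized with a warning.

The query service is a stateless, read-only WSGI application over a
loaded bundle; every endpoint is a thin JSON view whose numeric payload
equals the corresponding library call exactly. An id absent from a
released table yields empty results — the service cannot (and does not
claim to) distinguish "never observed" from "excluded for privacy".
Vocabulary-mapping endpoints require a concept-relationship extract and
otherwise return a structured "vocabulary not loaded" notice; ontology
cross-referencing against external services is out of scope.

## Numerical and degenerate-input choices

- `prevalence` and `relative_frequency` raise on zero denominators;
  randomized numerators above the denominator are allowed and documented.
- `log_ratio` signals zero pair counts instead of returning −∞.
- Chi-square uses `scipy.stats.chi2_contingency(correction=False)`; the
  test suite cross-checks it against explicit `(O−E)²/E` cell arithmetic.
- Concept names longer than OMOP's 255-character limit either raise or
  truncate, per a reader flag.
- Date parsing failures are per-row errors naming the line, with a
  configurable fail/skip policy and exact reconciliation of row tallies.
- All randomness flows from explicit integer seeds through numpy
  `SeedSequence`; derived entropy words stay below 2³².

## Known limitations

No hierarchy-aware rollup (descendant concepts are not aggregated into
ancestors), no temporal-window co-occurrence, no unstructured-note
concepts, no formal differential-privacy accounting — the Poisson
randomization is a pragmatic perturbation, not a privacy proof. EHR
prevalence reflects healthcare consumption at the source institution,
not general-population prevalence.
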