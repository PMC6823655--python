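# Methods

## Scope and intent

`carecomplexity` computes nine-domain biopsychosocial complexity
profiles and composite scores for community health-center clients from
linked multi-source record bundles. It is a rule engine, not a fitted
statistical model: every score is a deterministic function of the
client's records, the analysis window and the configuration. The rules
encode clinical-operational judgement (which data elements indicate
complexity, and how strongly), so the package's job is to apply them
transparently, reproducibly and at population scale.

## Record model and linkage

Eight record types are linked by exact client id: encounters
(with booked/attended status), HoNOS assessments (12 items, 0–4),
problem-list diagnoses, vitals (BP, BMI), ED visits with CTAS triage
level, acute admissions, administrative flags (PWD forms, SHX codes,
InterRAI-MDS, mobility assessments, violence alerts, Extended Leave)
and PHQ-9 totals. Probabilistic linkage is out of scope: a client with
different ids in different systems is treated as two clients, which
understates complexity for exactly the transient population most
affected — a real limitation of id-based linkage generally.

**Analysis window.** "Past 18 months" is computed in calendar months
(as-of date minus 18 months via calendar arithmetic, day clamped to
month length), not a fixed 548 days; the window is half-open at the
start and inclusive of the as-of date. Utilization and assessment
records (encounters, HoNOS, vitals, ED visits, admissions, PHQ-9) are
window-filtered; the problem list and status flags are current-state
descriptions and pass through unfiltered. An admission is retained
when its stay intersects the window, and an open admission accrues
length of stay up to the as-of date (an in-hospital client is maximally
acute). Vitals are treated like the other dated observations ("latest"
means latest in-window), by analogy with the HoNOS handling.

**Ties.** When two assessments share the latest date, the one with the
higher total (item sum for HoNOS, total for PHQ-9) wins — the
deterministic, complexity-preserving choice.

## Scoring rules and their interpretation

Several rules required one documented reading where the source rules
are terse:

- **AND/OR over HoNOS items** is implemented as the maximum over the
  listed items: the only reading that yields a single 0–4 value per
  domain and is monotone in every item.
- **Q1 visits** are attended encounters only; a booked no-show is not a
  visit. "Equally dispersed" is operationalized entirely by the
  collapse rule: sorted dates are scanned greedily and a date is
  dropped when it falls fewer than 7 days after the last retained date.
  A same-week flurry of contacts therefore counts as one act of
  engagement.
- **Q2** counts distinct programs with at least one attended in-window
  encounter; simultaneously open referrals are not separately modelled.
  More than 10 no-shows with booked appointment adds 1, clamped at 4.
- **Presence triggers** (PWD forms, SHX codes, InterRAI-MDS, mobility
  assessment, violence alerts, Extended Leave, PHQ-9 > 9) set their
  domain to exactly 4, dominating the HoNOS base.
- **Q7** uses highest-matching-tier precedence (the tier ladder is
  deliberately non-monotone in diagnosis count: 4+ plain diagnoses →
  tier 1, but any SU/MH diagnosis → tier 2), then adds modifiers:
  +1 for more than 5 diagnoses, +0.5 for latest BP above 140/90
  (systolic **or** diastolic), and the single highest applicable BMI
  increment (+0.25 / +0.5 / +0.75 above 25 / 30 / 35). The sum clamps
  to [0, 4]. Medication counts and PSW forms appear in source systems
  but carry no scoring rule and are excluded.
- **Q8**: the hospitalization complexity score is Σ(6 − CTAS) over ED
  visits plus Σ LOS days over admissions — the simplest form with the
  required monotone behaviour in acuity and stay length (both terms are
  exposed through config-adjacent code, so alternatives are pluggable).
  The printed score bands overlap at their anchor points; they are
  resolved as 0 / (0, 15) / [15, 25) / [25, 50] / > 50 with the higher
  score winning on overlaps — deterministic, monotone and faithful to
  the anchors 15, 25, 50.
- **Missing data** contributes 0 and clears the domain's completeness
  flag; it is never an error. Attachment (Q1) is the exception: the
  absence of visits *is* the attachment signal, so Q1 is always
  flagged complete. A consequence worth knowing: an all-4 profile is
  not jointly attainable, because the attended visits needed to
  maximize service density (Q2) are themselves attachment (driving Q1
  to 0). The `max_triggers` fixture documents this: Q2–Q9 all reach 4
  while Q1 is 0.

## Composite and weighting

Q-scores are divided by 4 and combined by root sum squared, giving a
composite in [0, 3] with the maximum attained exactly at the all-4
profile. Weights multiply the adjusted values inside the root sum
square — the only placement under which +20% / −25% on three domains
each keeps the maximum ≈ 3 (√(3(1.2² + 1² + 0.75²)) ≈ 3.00125).
Weighted scores are deliberately not re-normalized to exactly 3.

Weight derivation takes a domain × rating count table from a five-point
importance survey and tiers domains by the fraction rating Important or
Very Important. The shipped thresholds are ≥ 2/3 → 1.20 and < 1/3 →
0.75 with 1.00 between; the exact rule that produced the operational
middle tier is not published, so the thresholds are configuration, and
a two-tier scheme (high/low only) is supported by setting the low
threshold to none. The derived config records the thresholds used in
its provenance note.

## Synthetic cohorts

The generator exists because no client-level data for this population
are published. It emulates the *structural* features the scorer
consumes — multi-program encounter streams with bookings and no-shows,
HoNOS item distributions, problem lists drawing from the configured
code lists, vitals, CTAS-graded ED visits, admissions with exponential
stays, flag prevalences, PHQ-9 totals — for three illustrative
archetypes: a low-complexity youth-clinic/specialty-program user, a
high-complexity multi-program client with SU/MH burden and housing
instability, and a frail senior with ADL needs and admissions.
Archetype parameters are illustrative, not estimates of any real
population; passing cohort-level tests therefore demonstrates that the
pipeline preserves ordering and conservation properties, not that it
reproduces any site's real distribution. Features of real data that
are *not* emulated include cross-source id mismatch, temporal trends
within the window, correlated missingness, and free-text problem
labels.

Each client draws from an independent `numpy` stream seeded by
`(cohort seed, client index)`, so bundles are byte-reproducible and
archetype assignments are stable when the cohort grows. Default
problem-list codes are drawn from the shipped placeholder code lists so
that code-list-based category resolution is exercised end to end.

## Numerical and interface choices

- Scores are exact small floats (integers and quarters); comparisons in
  tests use 1e-12 tolerances only where root-sum-square arithmetic is
  involved.
- Bundle validation is pydantic-based, with row-level diagnostics
  naming table, row and field; a JSON Schema document for the bundle
  format ships alongside for consumers who validate externally.
- Composite band reports use half-open bands [0, 1), [1, 2) with the
  top band closed; domain-level bands likewise on the 0–4 axis. Band
  counts always sum to the cohort size.
- The shipped SU/MH, complex-care and neurodegenerative code lists are
  small documented placeholders (the operational complex-care list is
  maintained by a provincial committee and not redistributed);
  deployments must substitute their own lists via `ScoringConfig`.
- "Real time" means on-demand recomputation: the CLI re-reads the
  bundle and recomputes everything on each invocation, logging record
  counts and completeness rates per run.

## Test design

Unit tests pin every rule anchor with hand-built records. Property
tests (seeded) check bounds, monotonicity, flag dominance, window-filter
idempotence and record conservation. Two independent brute-force
oracles — a straight-line enumeration of the rule table with its own
calendar arithmetic, and a direct evaluation of the composite formula —
are compared against the implementation on randomized virtual patient
records (10,000) and random q-vectors (100,000); these sizes keep the
full suite under a minute on one core while leaving the agreement
checks overwhelming. Cohort-level checks run at n = 400–5,000, sizes at
which binomial mixture-recovery bands and archetype mean orderings are
sharp.

## Known limitations

- Exact-ID linkage (above); no de-duplication across systems.
- The rule weights and thresholds encode one organization's judgement;
  portability to other settings requires re-deriving weights and
  possibly re-anchoring rules (the low-complexity end of the scale is
  known to be coarse: most of a general-practice population would score
  in 0–1).
- Q7's tier ladder is literal, including its non-monotonicity in
  diagnosis count.
- HoNOS/PHQ-9 scores are taken at face value; no adjustment for
  assessor effects or assessment age within the window beyond
  "latest wins".
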