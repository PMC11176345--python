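# Methods

## The reimbursement model

The package models activity-based funding for multi-centre cohort studies.
Every study activity (documenting a ward day, taking an ECG, processing a
PBMC sample, uploading an imaging series) is a *reimbursement item* with a
fixed lump sum. An item's price is composed of per-role time efforts —
study personnel (SP), physician (PH), medical specialist (MS) — priced at
tariff-derived per-minute rates, plus material costs, scaled by an optional
overhead fraction:

    price(item) = round2( (Σ_roles round2(cost_role) + round2(material)) × (1 + overhead) )

Each component is rounded to cents (half-up) *before* summation; this is the
convention that reproduces the packaged catalogue's published row totals.
Where an explicit per-role component cost is stored it takes precedence over
`minutes × rate`. This matters because the MS rate is activity-dependent in
the reference catalogue (1.117–1.2053 €/min across items), so a single global
MS rate cannot reproduce all rows; the packaged catalogue therefore stores
explicit component costs for every effort and global per-minute rates only
for SP (0.5498 €/min) and PH (0.8027 €/min). The reference catalogue's
"salary %" tariff column is kept as opaque provenance metadata
(`tariff_percent_per_min`), not interpreted.

Two rows of the reference catalogue are internally inconsistent at the cent
level (screening/baseline documentation: components sum to 116.00 € against a
published total of 115.00 €; echocardiogram: 83.53 € vs 83.52 €). The
catalogue stores the published components, prices from them, and keeps the
published total in `printed_total_eur` metadata rather than silently
resolving the conflict.

Visit types are defined as item multiplicities; the cost of a case is the sum
over its documented visits. The *case fee* — the expected mean reimbursement
per case, used by the fixed-rate comparison — is either a configured constant
(defaults: HAP 12,871.70 €, POP 3,400.76 €, SUEP AMC 2,904.67 €, SUEP non-AMC
1,071.23 €) or the expectation over a distribution of visit paths.

## Data model and quality gates

Three pseudonymised systems feed the engine: clinical documentation (eCRF),
biosampling, imaging uploads. A linkage table in the style of a trusted third
party maps per-system pseudonyms onto one case; no identity fields exist
anywhere in the model. The eCRF anchors reimbursability: bio/imaging records
without an eCRF-anchored case are reported as orphans and never billed
(report-and-continue, because partial uploads are normal in practice).

A case is *recruited* when consent is registered and *reimbursable* when all
required forms are submitted (baseline + discharge, or initial interview +
on-site for the population cohort) and, where the cohort demands it, every
required sub-form passed its local case review. A non-reimbursable case
yields zero billable lines; partial payment is deliberately not modelled.
Record-level gates then apply: submitted ∧ plausibility-passed for eCRF
items; registered ∧ matching sample-type rule ∧ aliquot count ≥ minimum for
biosamples; uploaded ∧ ≥ 1 series ∧ matching modality rule for imaging.

Exclusions use a closed coded vocabulary (NO_CONSENT, FORMS_MISSING,
CASE_REVIEW_MISSING, PLAUSIBILITY_FAIL, ALIQUOTS_BELOW_MIN, NOT_UPLOADED,
UNMAPPED_ITEM) so that reports are machine-diffable. Coding conventions where
the vocabulary had to be stretched: an unsubmitted record is bucketed as
FORMS_MISSING; an unregistered biosample as NOT_UPLOADED; a sample type or
modality without a configured rule as UNMAPPED_ITEM. Every excluded record
lands in exactly one bucket, and survivors + exclusions = total (tested as an
invariant). A failing biosample or imaging record suppresses only its own
fee, never the whole visit's.

Surviving eCRF items map to catalogue items through a reviewed mapping table
with per-row conditions (`always`, `value-present`, `plausibility-pass`);
unmapped items are counted and reported, never billed.

## Imputation of announced visits

Visits announced for the reimbursement period but due after the
documentation freeze are imputed: one flagged line per
announced-but-undocumented visit, valued at an *experience value* — the mean
cost of completed visits of the same type, resolved centre-level first, then
cohort-level, then a configured default, with the provenance logged per line.
Experience values are learned from the current run's non-imputed lines.
Imputation never alters non-imputed lines, and disabling it reproduces the
pre-imputation totals exactly (tested).

## Aggregation, reports, audit

Centre summaries carry recruited/reimbursable counts, totals, mean per case,
the share of each source system, follow-up fulfilment (documented / expected
FU visits, reported as a percentage, absent when nothing was expected), and
the study initiation fee — granted only to SUEP non-AMC centres with ≥ 5
reimbursable cases, with a configurable amount since no published figure
exists. The initiation fee is kept out of the per-case mean (it is not
case-derived) and reported both separately and in a grand total.

All amounts are `decimal.Decimal` fixed-point; cohort = Σ centres = Σ cases =
Σ lines holds exactly on every run. Reports (CSV + Markdown) are scoped per
audience — a centre sees only its own cases, coordination sees everything —
and are derived purely from run content, so regeneration is byte-identical.
Every run carries a ledger with SHA-256 input digests and an iteration
counter; correction loops are new runs, not in-place edits. The audit sample
is a uniform draw without replacement under an explicit seed (default 10
cases).

## Funding-model comparison

- **FRM**: case fee × reimbursed cases. Its percent-of-PBRM is computed
  uncapped; with identical capping on both sides it reduces to the per-case
  ratio fee / mean, so the cap cancels and the published per-case ratios are
  reproduced directly.
- **UFAM**: quarter-rounded FTE staffing (physician + study nurse, ties away
  from zero) × FTE costs + consumables × *target* cases. A per-centre lump
  sum may be supplied instead of the FTE composition, since published
  outcomes exist per centre but staffing inputs do not. The UFAM
  percent-of-PBRM uses the capped reference: over-recruiters are capped at
  target × mean per case, because an up-front-funded centre would have
  stopped at its target. The interpretation of the staffing sentence is
  `staffing + consumables × target` (multiplying staffing itself by the
  target would make per-centre funding quadratic in the target, which is not
  meaningful).
- **Cost-efficiency**: cases per 10,000 € budget unit. Per centre:
  budget / effective cost per case (PBRM: mean per case; FRM: the fee; UFAM:
  funding / min(n, target)). The cohort value is the mean of per-centre
  ratios with a two-sided t-based 95 % CI — the alternative (budget divided
  by the cohort mean cost) yields the same values at one decimal for the
  published inputs but is not used. The CI construction in the source
  material is not fully consistent (one published interval is incompatible
  with a centre-level t-interval), so CIs are reported but not treated as
  exact targets.
- **ANOVA**: classical one-way between/within mean-square F with its p-value
  from the F distribution. Degenerate inputs are resolved explicitly —
  identical constants give (F = 0, p = 1), zero within-group variance with
  real separation gives (F = ∞, p = 0) — which is why the sums of squares are
  computed directly rather than delegated; `scipy.stats.f_oneway` serves as
  the cross-check oracle in the tests.

SUEP non-AMC centres are excluded from the model comparison by default
(different financing structure).

## The synthetic-cohort generator

The generator emulates the structure the engine is designed for, not the
clinical content (eCRF values are opaque tokens):

- **Recruitment heterogeneity**: per-centre counts drawn lognormal and
  clipped to [1, 164] by default, spanning the single-case to >150-case range
  observed across real centres; explicit counts can be supplied.
- **Severity**: inpatient paths are baseline + ward days + optional ICU days
  + discharge. Lengths of stay are geometric by default (memoryless
  discharge; no published law exists), negative binomial as an alternative.
  The population cohort has exactly one initial interview and one on-site
  visit per case.
- **Follow-up**: each scheduled FU visit is announced; it is documented with
  probability `fu_compliance` (defaults per preset: 0.5 inpatient, 0.63/0.7
  cross-sectoral — within the 50–70 % range seen in practice), suppressed by
  dropout, or pushed past the documentation freeze with probability
  `announced_post_freeze` to exercise imputation.
- **Quality noise**: per-form missing-documentation and case-review-failure
  probabilities, per-record plausibility failures, Poisson aliquot counts
  (which can fall below the minimum), and imaging upload failures.
- **Pseudonym namespaces** are disjoint per system (`E…`, `B…`, `I…`) so the
  linkage step is genuinely exercised.

Each bundle ships a ground-truth table (eligibility and the exact
reimbursable amount per case) accumulated during generation directly from the
record flags and catalogue prices — the engine pipeline is never invoked to
produce it — so oracle tests compare two independent routes. For convergence
checks, `analytic_mean_case_cost` computes the expected per-case total in
closed form: the path-distribution expectation (geometric tails truncated at
10⁻¹² remaining mass, the truncation point absorbing the tail) plus closed-form
biosampling/imaging expectations; it refuses configs with record-level noise,
which would bias it.

What passing the simulation tests does **not** show: agreement with any real
cohort's per-centre means, follow-up rates or source shares — those depend on
unpublished data; the presets are calibrated only to the published extremes
(recruitment 1–164, targets 73.5 / 330 / 98.1, compliance 50–70 %). The SUEP
non-AMC recruitment target is unpublished; the preset uses 25 cases.

## Numerical choices

- Money: fixed-point decimals, half-up to cents per component; percentages
  half-up to one decimal. Currency never passes through binary floats.
- Quarter-FTE rounding: nearest 0.25, ties away from zero (0.875 → 1.0);
  idempotent and within 0.125 of its input (tested).
- FU fulfilment with zero expected visits is reported as absent, not 0.
- Statistics (CIs, ANOVA) are computed in floats after the exact decimal
  aggregation; `scipy.stats` supplies the t and F distributions.
- Problem sizes in tests and the acceptance script (bundles of tens of cases
  for exactness checks, 2,000 cases for convergence checks at three
  Monte-Carlo standard errors) were chosen as the smallest sizes at which the
  statistical checks are sharp.

## Known limitations

- Exact pseudonym matching only; no record-linkage heuristics, no real TTP
  cryptography, no DICOM parsing (imaging is upload metadata only).
- Plausibility checks are pluggable predicates; the shipped set
  (range/enum/date-order style flags in the synthetic data) does not attempt
  to reproduce any production check catalogue.
- No payroll/tariff-table management, currency conversion or inflation
  adjustment; no PDF rendering, invoicing or access-control enforcement
  beyond file scoping.
- The comparison assumes recruitment behaviour is unaffected by the funding
  model except through the cap for over-recruiters.
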