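# Methods

## The screen

`rorscreen` implements reporting-odds-ratio (ROR) disproportionality screening
for spontaneous adverse-event report databases of the JADER (Japanese Adverse
Drug Event Report) dialect: three delimited tables — demographics, drugs per
case with an involvement role (suspected / interaction / concomitant), and
reactions per case as MedDRA-style preferred terms (PTs) — linked by a case
identifier.

For an ADR of interest and a drug group of interest the screen counts analysis
units into the 2×2 layout

|                    | ADR of interest | other (non-TD/EPS) ADR |
|--------------------|-----------------|------------------------|
| drug of interest   | a               | b                      |
| reference drugs    | c               | d                      |

and reports ROR = (a·d)/(b·c). An ROR above 1 means the target reaction is
reported disproportionately often with the drug group of interest. It is a
signal-detection statistic on reports, not a risk estimate on patients.

## Case curation

The cascade, in order (each step a flow-accounted filter; input = excluded +
retained at every stage):

1. **Deduplication.** Reports are exploded into (case id, ADR term, drug name)
   triples; triples identical on all three keys are one case. Matching is
   case-insensitive after whitespace normalization; no fuzzy matching.
2. **Role filter.** Only *suspected* drug–ADR links are analyzed; interaction
   and concomitant links are dropped.
3. **Nonspecific terms.** ADR terms that are nonspecific or generically
   injection/antipsychotic-related are dropped. The default list ships the
   three canonical examples (long QT syndrome, anaphylaxis, injection site
   reaction) and is user-extensible — no authoritative full list exists, so
   the default is deliberately minimal.
4. **Pediatric exclusion.** Cases with age category fetus / neonate / infant
   are removed.
5. **Clozapine exclusion.** Movement-disorder (TD/EPS) cases in which
   clozapine appears in *any* role are removed: clozapine is reserved for
   treatment-resistant schizophrenia, so its reports are confounded by prior
   antipsychotic exposure. The role scope is a config switch
   (`clozapine_any_role`, default any role).

Per ADR of interest, a case carrying that term is an interest case; a case
carrying no TD/EPS term at all is a reference case; a case carrying a
*different* TD/EPS term is removed (competing movement-disorder case). A case
carrying the term of interest plus another TD/EPS term is retained in its own
screen and removed from the screens of terms it does not carry — the source
analyses do not pin down multi-term handling and this is the minimal reading
that keeps every term's screen well defined.

**Unit granularity.** A unit is a distinct (case, suspected drug) pair, so one
case contributes under every suspected drug it names — deliberately, since
report-level screens count this multiplicity — but only once per cell. ROR
analysis sets additionally drop units with unknown sex or unknown binary age
(complete-case requirement of the adjusted model and the stratified screen);
demographic tables keep unknowns as their own rows.

## Exact inference

Conditioning on both margins of the 2×2 table, the target cell follows
Fisher's noncentral hypergeometric law with odds parameter ψ. The package
computes:

* the two-sided exact p under ψ = 1 by the minimum-likelihood rule (summing
  probabilities of all tables no more likely than the observed one; delegated
  to `scipy.stats.fisher_exact`, which implements exactly this rule);
* exact conditional (Cornfield) limits by inverting the conditional tails:
  lower limit solves Pr(A ≥ a | ψ) = α/2, upper limit Pr(A ≤ a | ψ) = α/2.
  Tails are evaluated from max-shifted log-space weights over the support and
  the roots located with Brent's method on log ψ (xtol 1e-9; bracket seeded
  from a Haldane-corrected Woolf interval purely as a speed-up — an expansion
  loop guarantees the bracket regardless). When `a` sits at the support
  minimum the lower limit is 0; at the maximum the upper limit is +∞; a
  single-point support (zero margin) has no information and yields an
  undefined pair.

Zero cells are never continuity-corrected. The crude screen follows the
publication conventions for degenerate rows: a zero target cell prints
ROR 0 (or NA when both target cells are zero) with an undefined interval
("NA-NA") and classifies as *undetermined*. The asymptotic log-scale (Woolf)
interval and the conditional maximum-likelihood odds ratio are available as
options; the defaults are the exact interval and the cross-product point
estimate, which is the standard ROR definition in pharmacovigilance.

**Signal rule.** Lower 95% limit above 1 → signal for the drug of interest;
upper limit below 1 → signal for the reference; undefined interval →
undetermined. No multiplicity adjustment is applied across the screen grid by
default (mirroring standard practice in these screens).

## Adjusted RORs

The adjusted ROR is the exponentiated exposure coefficient of a
maximum-likelihood logistic model on the analysis units: outcome = ADR of
interest vs reference ADR; covariates age (≥60 = 1), sex (female = 1), report
period (2016–2020 = 1), concomitant anticholinergic and lithium use, plus
concomitant FGA use for SGA-exposure screens and concomitant SGA use for
FGA-exposure screens. Reference levels: male, age <60, 2011–2015, no
concomitant use. Confidence limits are Wald intervals on the log-odds scale.
Fits use an iteration cap of 100; a fit whose exposure coefficient exceeds 15
in absolute value on the log-odds scale is reported as *separated* with the
conventional 0.00–Inf bounds instead of a spurious finite estimate — matching
how unpenalized fits on separated screens are conventionally printed. No
penalization (e.g. Firth bias reduction) is applied by default.

## Synthetic reporting-system generator

The generator emulates the statistical structure the screen assumes: reports
with demographics (sex, categorical age including pediatric categories,
report date in the 2011–2020 window), a focal suspected drug, class-correlated
concomitant co-use (anticholinergics, lithium, cross-generation
antipsychotics), optional extra drugs in any role, per-term Bernoulli ADR
assignment with log-odds additivity across suspected drugs and planted
covariate effects (movement terms only), configurable missingness, and
duplicate row emission. Reports are resampled until they carry ≥1 term,
because reaction-free reports cannot exist in a reporting system; the induced
scaling of marginal term frequencies (by 1/P(any term)) cancels in every odds
contrast, so planted odds ratios remain the screen's exact estimand when a
single effect is planted and suspected drugs do not co-occur.

What it does **not** emulate: reporting-delay dynamics, masking/competition
bias, dose, indication, or real polypharmacy correlation structure. Passing
calibration and recovery tests therefore demonstrates correctness of the
pipeline's accounting and inference under the generator's model — not that
real spontaneous-report data satisfy that model.

Named scenarios (all fully seed-deterministic; identical config + seed gives
byte-identical files):

* `paper_shaped_scenario` — 13 TD/EPS terms (baseline 0.004), 10 reference
  terms (0.045), 3 nonspecific terms, FGA/SGA(g1–g4)/anticholinergic/lithium
  menus, planted effects ordered FGA > SGA for TD (12 vs 6), dyskinesia
  (8 vs 4) and parkinsonism (10 vs 4), equal for the rest.
* `null_calibration_scenario` — same menus, no effects, movement baselines
  raised to 0.02. Rationale: at realistic baselines the null screen's target
  cells hold only a handful of counts, where exact conditional intervals are
  guaranteed-conservative (empirical coverage near 99–100%); no exact method
  can show ~95% coverage there. The raised baseline puts median cell counts
  at ≈8–60, where discreteness is negligible and the interval's nominal
  behavior is actually testable.
* `recovery_scenario` — slim menu, one planted effect
  (FGA → tardive dyskinesia), no co-suspected drugs, so the planted
  conditional OR equals the screen estimand exactly.

## Study sizes

Frozen study designs used by the test suite and the acceptance script
(chosen once for statistical resolution at single-CPU scale):

* exact-inference oracle equivalence: exhaustive over all 2×2 tables with
  N ≤ 40 (~135k tables); p-values against direct enumeration (≤1e-12), CI
  limits against an independent grid+bisection oracle (≤1e-6 relative);
* null calibration: 200 replicates × 10 000 reports; per-cell signal rate
  ≤ 10%, pooled exact-CI coverage of OR = 1 within 93–97%;
* crude-OR recovery: planted OR 5.0, 300 replicates × 20 000 reports,
  coverage ≥ 89%;
* logistic recovery: exposure 1.6, age 0.4, sex −0.2 on 20 000 units × 300
  replicates; exposure mean bias ≤ 0.1, Wald coverage ≥ 89%;
* conservation/idempotence property suite: 100 random databases × 250
  reports.

## Numerical and degenerate-input choices

* Exact-CI root finding: relative tolerance ~1e-9 on ψ; ties in the minlike
  p-value at relative tolerance 1e-14 (scipy's convention).
* Empty analysis sets yield all-zero tables, which analyze to undetermined
  rows rather than raising.
* Unclassified drug names map to class "other" (hence the non-antipsychotic
  reference pool) and are never silently reclassified; the classification
  table's checksum is recorded in every screen's metadata because the shipped
  default roster is a reconstruction, not an authoritative list.
* Dates outside 2011-04-01..2020-03-31 are rejected at load; the column that
  defines the report date is a dialect-config choice because reporting
  systems carry several candidate date fields.
* Constant covariate columns are dropped with a warning; a constant outcome
  or exposure is an error (no estimable contrast).

## Known limitations

* The default drug-classification table is reconstructed from the
  pharmacology-based grouping scheme (NbN: g1 dopamine+serotonin antagonists,
  g2 +norepinephrine, g3 multimodal, g4 partial agonists); exact reproduction
  of any published screen requires that study's own roster.
* Adjusted RORs on real published screens are not reproducible without
  case-level covariate data; the adjusted model is validated by recovery
  studies instead.
* The brand-name → generic mapping, MedDRA hierarchy traversal and SMQ
  expansion are out of scope; inputs are assumed to be generic names and
  preferred terms.
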