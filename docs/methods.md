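# Methods

`pvsignal` implements desk-scale disproportionality analysis for spontaneous
adverse-event reporting databases of the FAERS type, together with a
synthetic report generator that makes the whole chain testable against a
known truth. This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic benchmark does and
does not demonstrate.

## The statistical model

Every analysis reduces a curated database of N reports to a 2×2 table for a
(drug query, endpoint) pair:

|                 | endpoint | no endpoint |
|-----------------|----------|-------------|
| query-exposed   | a        | b           |
| all other reports | c      | d           |

The comparator is always *all other reports in the curated database*; there
is no restriction to a comparator drug class, and counting is report-level
(a report mentioning a query drug twice counts once).

On this table the package computes:

* **ROR** = (a·d)/(b·c) with the Woolf (log-normal) 95% CI
  exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)). Any zero cell makes the
  estimate or its variance undefined; the result is then reported
  *not estimable* (NE). A Haldane–Anscombe +0.5 mode exists behind the
  `continuity` option but is off by default, because an explicit NE outcome
  for zero-count combinations is part of the result, not a nuisance.
* **PRR** = [a/(a+b)] / [c/(c+d)], NE when a+b = 0 or c = 0.
* **RRR** = a/E with E = (a+b)(a+c)/N, the observed/expected ratio.
* **Yates χ²** = N(|ad−bc| − N/2)² / ((a+b)(c+d)(a+c)(b+d)), floored at 0
  when |ad−bc| ≤ N/2; used only by the Evans screen.
* **Fisher exact p** (two-sided, minimum-likelihood rule): conditional on
  the observed margins, p sums the hypergeometric probabilities of all
  tables no more likely than the observed one, with a 10⁻⁷ relative
  tolerance absorbing floating-point ties. The enumeration is implemented
  in-package over the full support (log-factorial table); it is exact and
  deterministic, and remains defined for degenerate margins (p = 1). The
  association p-value is always the Fisher p; χ² is never used for p.
* **Information component** IC = log₂((a+½)/(E+½)). The +½ shrinkage is the
  gamma-posterior stabilisation that pulls small-count cells toward the
  database mean, damping notoriety- and early-marketing spikes. Its lower
  95% credibility bound is, by default,
  IC025 = log₂(q/(E+½)) with q the 2.5% quantile of Gamma(shape a+½,
  rate 1) (`ic_mode="quantile"`); the widely used closed-form approximation
  IC − 3.3(a+½)^(−1/2) − 2(a+½)^(−3/2) is available as `ic_mode="approx"`.
  Across all tables with cells ≤ 30 the two modes agree within 0.15 for
  a ≥ 1 (observed maximum gap ≈ 0.05), and IC025 < IC always.
  Different platforms compute IC variants that differ in exactly this
  choice, so numerical identity with any particular external tool is not
  asserted.
* **Evans screen**: a > 2 AND χ² > 4 AND ROR > 2, all strict; an NE ratio
  fails the screen. The ratio compared against 2 is the ROR by default
  (`evans_metric="prr"` selects the classical PRR variant).
* **Signal rule**: SIGNAL iff p < 0.05 AND IC025 > 0 (strict); a pair with
  no cases at all (a = 0, ROR not estimable) is classified NOT_ESTIMABLE;
  everything else is NO_SIGNAL.

No multiplicity adjustment is applied across the (query, endpoint) grid;
the run metadata states this explicitly so downstream readers are not
misled.

### Numerical conventions

The four ratio statistics are evaluated as a single float division of
exactly representable integer products, so for integer cells the returned
double is the correctly rounded value of the underlying rational number —
the test suite verifies this exhaustively for all cells ≤ 30 and by
`fractions.Fraction` spot checks. NE is represented as `None` in the scalar
API and `NaN` in the vectorised helpers; exported CSVs print the literal
`NE`. Result files are written with fixed formats (ratios at 2 decimals,
p-values in scientific notation below 10⁻⁴, Unix newlines), which makes
repeated runs byte-identical.

## Case selection

Drug queries come in two modes. `PRIMARY_SUSPECT_ONLY` requires one of the
query drugs to be the report's designated primary suspect — the stricter
attribution used for single-drug analyses. `ANY_ROLE` accepts any reporter
role; with `combination=True` every query drug must co-occur on the report,
the sensitivity-maximising design for co-reporting questions (combination
queries therefore require `ANY_ROLE`). Reports containing the combination
plus other drugs still count as exposed: the question is co-reporting, not
exclusive exposure. An optional `exclude` set can bar reports mentioning
named drugs from the exposed group; by default nothing is excluded (a
lithium query does not exclude semaglutide co-mentions, and vice versa).

Endpoints are named sets of MedDRA preferred terms matched by exact string
equality after trimming and case-folding. There is no MedDRA hierarchy
traversal: endpoints are explicit PT lists by design.

## Curation

1. **Normalization.** Verbatim drug names are trimmed, case-folded and
   looked up in a synonym map (brand names, salt forms, abbreviations →
   canonical lower-case name). Unmapped names are flagged unresolved but
   *retained*: dropping them would silently shrink the comparator
   background. Normalization is idempotent.
2. **Validation.** A report is excluded when (checked in this fixed
   precedence, one primary reason per record): receipt date missing or
   outside the closed analysis window; empty drug list; empty reaction
   set; negative age. Missing age or country are tolerated. The default
   window is 2003-12-01 through 2024-12-31, month boundaries interpreted
   as full first/last days.
3. **Deduplication.** Records sharing a `case_id` are versions of one case
   and form a group. Otherwise records are grouped on the tuple (sex, age
   rounded to whole years, country, sorted normalized drug names, sorted
   reaction PTs) — the demographic and case-level variables a re-submission
   preserves; rounding the age tolerates unit jitter. Each group keeps the
   latest receipt date, ties broken by smallest report_id, making the
   retained set independent of input order. The counts always satisfy
   n_input = n_output + n_excluded + n_removed.

The duplicate key and the keep-latest/smallest-id tie-break are declared
conventions: reasonable alternatives exist, but determinism requires fixing
one, and the synthetic benchmark scores this exact rule.

## The synthetic report generator

The generator emulates the *structure* of a spontaneous reporting system,
not the pharmacology of any real one. Per primary report: receipt date
uniform in the window; age ~ round(Normal(52, 17)) clipped to [18, 90]; sex
M/F/U at 0.43/0.52/0.05; country from a small weighted list; each catalog
drug present independently with its marketing probability (empty drug sets
are redrawn — a spontaneous report exists to implicate a drug); one present
drug is chosen uniformly as the primary suspect, the rest draw SS/C/I from
the renormalised role distribution; each drug mention carries a verbatim
alias chosen uniformly from its catalog aliases.

Reactions follow a per-PT independent Bernoulli model on the logit scale:

    p(PT j | drugs D) = logit⁻¹( logit(baseline_j) + Σ_{i∈D} ln θ_ij )

This is the simplest model in which a configured odds multiplier θ *is* the
true reporting odds ratio between exposed and unexposed reports, which is
what makes parameter recovery well defined. Reports whose reaction vector
comes up empty are redrawn; the default catalog keeps P(empty) ≈ 1.5×10⁻³,
so the induced inflation of each PT marginal (factor 1/(1−P₀)) is an order
of magnitude below the 3-Monte-Carlo-SE calibration band at n = 50 000.

Contamination is exact-count: round(duplicate_rate·n) near-duplicate clones
(identical fields, new report and case ids, receipt date shifted by ≤ 30
days within the window) and round(invalid_rate·n) corrupted copies (drug
list emptied, reaction list emptied, or age set to −1, uniformly). Default
rates are 5% duplicates and 2% invalid — fixture choices, since no
authoritative contamination rates exist for the emulated regime. The ground
truth records every planted θ, clone parentage and invalid id.

Random draws are consumed in a fixed field-major order (dates, ages, sexes,
countries, drug matrix with empty-row redraws, per-drug alias indices, PS
picks, role matrix, reaction matrix with empty-row redraws, duplicate
sources and shifts, invalid sources and modes), so a config with its seed
reproduces byte-identical tables across runs.

### Default catalog and why

Ten drugs (marketing probabilities 0.03–0.20; the two study drugs at 0.04
and 0.03 with brand/generic/case variants) and 35 PTs: five renal endpoints
with baselines 0.002–0.008 and thirty background symptom terms
(0.05–0.45). Two considerations fixed these numbers a priori:

* **Identifiability.** The benchmark recovery condition plants θ = 8 on one
  drug–endpoint pair at n = 200 000 and expects the point ROR inside
  [7, 9] in ≥ 90% of seeds. That requires SE(ln ROR) ≈ √(1/a + 1/c) small
  enough, i.e. expected a ≈ several hundred; marketing 0.04 × baseline
  0.008 gives E[a] ≈ 480 and SE ≈ 0.05, leaving comfortable margin.
  FAERS-realistic prevalences (drug mentions at fractions of a percent)
  would require databases far beyond desk scale for the same precision —
  this is a deliberate scaling of rates, not a claim about real frequency.
* **Non-empty reactions.** The background PT mass (Σ −ln(1−p) ≈ 6.5) keeps
  empty reaction vectors at the ~10⁻³ level discussed above. The price is
  a mean of ≈ 5 reactions per report, denser than typical real reports.

The default planted pattern used by the worked example mirrors the shape of
a two-drug renal-safety study: θ = 8 on all five renal PTs for the mood
stabiliser, θ = 0.5 on four of them (neutral on acute kidney injury) for
the GLP-1 receptor agonist.

## What the benchmark shows — and does not

Passing the synthetic benchmark demonstrates: the statistics are exact on
their formulas; the Fisher enumeration matches an independent
implementation; the signal rule behaves correctly on statistic pairs that
exercise each of its branches; curation removes exactly the planted
contamination (100% clone recall, false removals only on genuine key
collisions, which at n = 10⁵ with the default catalogs occur at the
10⁻⁴ level); planted effects are recovered with nominal CI coverage; and a
null database produces false signals at well below the 5% bound (the joint
p/IC025 rule is conservative).

It does not demonstrate robustness to features of real spontaneous-report
data that the generator deliberately omits: reporting dynamics over time
(Weber effect, notoriety spikes), country- or reporter-specific propensity,
correlated reaction terms, dose/duration fields, multi-version case
threading beyond shared case ids, misspelled or free-text drug names beyond
the synonym map, and confounding by indication or channeling. Inverse
associations in particular must not be read as protection: an IC025 below
zero indicates absence of disproportionality, nothing more.

One subtlety the benchmark *does* expose: under a primary-suspect-only
query, reports carrying the drug in a non-suspect role sit in the
comparator with their elevated event odds, so the PS-filtered ROR
systematically underestimates the planted any-role θ (by roughly 10–30%
under the defaults depending on co-mention patterns). Recovery is therefore
scored with an any-role query, for which θ is the estimand; the PS-filtered
study rows remain well above threshold and classify SIGNAL.

## Problem sizes

The shipped test suite runs the exhaustive oracle sweeps at cells ≤ 30
(923 k tables), the Fisher cross-check exhaustively at N ≤ 30 plus 3000
random tables to N = 200, planted-effect recovery at n = 200 000 × 100
seeds, and null calibration at n = 50 000 × 100 seeds (10 drugs × 5
endpoints per run; CI coverage pooled over pairs with expected a ≥ 20,
where the Woolf interval's asymptotics apply). `scripts/acceptance.py`
re-runs the same three study workflows at reduced sizes (60 000-report
study run; 10-seed recovery at n = 100 000; 30-seed null at n = 20 000),
sizes chosen as the package's own desk-scale defaults.
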