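# Methods

## Problem and scope

`pgxselect` addresses a resource-allocation problem in clinical
pharmacogenomics: a payer or health system can fund genotyping for a
fixed number of patients (a few hundred) out of an insured population of
thousands, and must pick the patients for whom testing is most likely to
change care. The package implements, on top of pharmacy/medical claims
tables, two selection strategies — a manual count of program-list
medications and an automated interaction-probability (PIP) score — plus
the eligibility cascade that defines the analyzed population, the
"natural cut" that turns a ranking into a cohort, and the statistical
panel used to compare two selected cohorts. Post-test interpretation
(genotype → dosing recommendation), EHR alerting and cost-effectiveness
modelling are out of scope.

## The knowledge base

Every clinically specific fact is data, not code: the eight-gene panel,
each gene's ordered phenotype ladder, population phenotype frequencies,
the medication lists of the two methods, per-drug actionable-phenotype
sets with interaction severities, inhibitor/inducer modifiers, and a
drug–drug interaction (DDI) severity table. The bundled fixture
(`data/default_kb.json`) carries 68 drug–gene rows over 61 medications:
34 rows shared by both methods, 9 manual-only (including warfarin under
CYP2C9, CYP4F2 and VKORC1), 25 automated-only (including metoprolol).
Membership is counted in drug–gene rows because a drug interacting with
several panel genes appears once per gene.

Two classes of fixture content are *placeholders by necessity*: the
actionable-phenotype sets and the phenotype frequencies. They follow the
shape of CPIC guidance (e.g. codeine–CYP2D6 actionable for ultrarapid
and poor metabolizers; clopidogrel–CYP2C19 for intermediate and poor;
North American-style frequency tables summing to 1 within 1e-9) but are
not a curated clinical resource, and nothing in the algorithms depends
on their specific values. Rules below moderate severity are rejected at
load: moderate is the lowest level with actionable recommendations. The
DDI table is a small curated set of well-known pairs (plus one
three-drug serotonergic rule) and deliberately excludes gene-mediated
interactions, which are unknown until test results exist.

## Claims ingestion

Pharmacy claims are keyed by 11-digit NDC and translated to
ingredient-level names through a local mapping table (`mapping.csv`),
standing in for an RxNorm lookup so the pipeline is deterministic and
offline; claims with malformed or unmapped NDCs (non-drug items such as
lancets) are dropped and counted. "Unique medications" always means
unique ingredient names — salts, doses and packages collapse.

The analysis window is a half-open date interval `[start, end)` (default
2018-10-01 to 2019-01-01, i.e. one calendar quarter); a fill on the end
date is outside. Eligibility applies four logged, sequential filters:
age ≥ 18 at window start; ≥ 1 pharmacy fill in the window; ≥ 1 in-window
fill for a medication on the union of the two method lists; complete
demographics (age and sex). The filter log also records how many
patients would survive without the panel-exposure filter, because
population-level medication marginals are naturally quoted against that
broader denominator; `filter_eligible(..., require_included_medication=False)`
computes it.

## Manual method

Each eligible patient gets the pair (count of unique manual-list
medications in window, count of all unique medications). Ranking is
descending on that pair; remaining ties are broken by one seeded uniform
draw per patient. Random keys are assigned against the id-sorted
population, so a (population, seed) pair yields one ranking regardless
of row order. The overall unique medication count includes non-panel
drugs — it is the profile-wide count.

## Automated method (PIP)

For gene *g* with phenotype frequencies `f_g`, the per-gene actionable
probability is

    p_g = Σ_φ f_g(φ) · 1[∃ d ∈ meds with rule (d,g):
                          eff(φ | meds ∖ {d}) ∈ actionable(d,g)]

and the score is `PIP = 1 − Π_g (1 − p_g)`, rounded half away from zero
to a whole percent. Because each gene's indicator depends only on that
gene's phenotype and the fixed medication list, the product form is
exactly the probability of "at least one actionable pair" under
independent genes — the test suite verifies this against exhaustive
joint-genotype enumeration to 1e-12. The number needed to test is
`NNT = 100 / PIP` (continuous, not rounded up). Bands: 0 none, 1–25 low,
26–50 moderate, ≥ 51 high — the low/moderate edge splits cohorts at
NNT 4, and above 50 a finding is more likely than not.

Design choices where the published description leaves freedom:

- **Victim restriction.** Only automated-list medications contribute
  rules to `p_g`; a warfarin-only profile scores PIP 0 even though the
  knowledge base carries warfarin rules for the manual method's use.
  Phenoconversion perpetrators are *not* restricted — inhibition is
  pharmacology, independent of which list a drug is on.
- **Phenoconversion.** A strong inhibitor maps genotypic NM, IM (and
  anything between them and PM on the ladder) to phenotypic PM; a
  moderate inhibitor shifts one step toward poor; a strong inducer jumps
  to the top of the ladder, a moderate inducer one step up. Only
  co-medications other than the victim convert the victim's gene
  (drug–drug–gene semantics). With several perpetrators the strongest
  wins; with an inhibitor and an inducer simultaneously present the net
  shift is taken to be zero — the simplest symmetric rule.
- **Independence across genes** is assumed; the commercial score's
  internal weighting is proprietary, so this formulation is a declared
  reconstruction of "probability of ≥ 1 clinically significant
  interaction", not a bit-compatible reimplementation.

Ranking is descending PIP, then DDI counts compared lexicographically
most-severe-first (contraindicated, severe, moderate, minor, minimal),
then total medication count, then the seeded random key. A DDI rule
fires only when its entire drug set is on the profile.

## Natural-cut selection

Candidate thresholds are the distinct score values; each implies the
cohort of patients scoring at or above it. The threshold minimizing
|cohort − target| wins; when two thresholds are equidistant the smaller
cohort is kept, conserving the testing budget. Cohorts are nested in the
threshold, and the selection is invariant to input order.

## Cohort comparison

Overlap is reported as a count and as a fraction of the smaller cohort
(plus Jaccard). Continuous metrics (medication count, moderate-or-higher
DDI count, PIP, ER cost, inpatient cost, age) use Welch's
unequal-variance t-test — the robust default given cohorts of unequal
size; binary metrics (≥ 1 moderate-or-higher DDI, ≥ 1 ER visit, ≥ 1
inpatient visit, female sex) use a pooled two-proportion z-test without
continuity correction. Cost means are taken over the whole cohort,
zero-cost patients included. All tests are two-sided, p-values
unadjusted. Degenerate inputs fail loudly and name the metric; two
zero-variance samples with equal means compare trivially (t = 0, p = 1),
as do proportions with a pooled rate of exactly 0 or 1.

## Synthetic populations

The generator emits the four tables the pipeline consumes. Per patient:
age from a normal (mean 35, SD 17.4 years) truncated at 18 by
resampling; sex female with probability 0.62; a count K of panel
medications from the pmf (0.267, 0.57, 0.131, 0.025, 0.007) for
K = 0,1,2,3,4; K distinct panel drugs sampled by Zipf-like popularity
weights with metoprolol, ondansetron and sertraline on top; Poisson(2)
background (non-panel) medications, with at least one medication forced
so every patient is active in the window; 1–3 fills per medication,
uniform over the quarter. ER (p = 0.08) and inpatient (p = 0.04) events
are Bernoulli with log-normal costs (log-scale 6.9 ± 1.0 and 9.3 ± 1.1);
cost scales are illustrative orders of magnitude, not calibrated. About
1.5% extra claims carry unmappable NDCs to exercise the drop path; they
are injected as additional rows, never by corrupting a medication's
fills, so the medication-count calibration is exact. Everything derives
from one `numpy` generator seeded by the config.

The pmf mass at K = 0 (0.267) is back-derived so that the ≥ 1 fraction
is 73.3% while the exactly-1/2/3 fractions are 57% / 13.1% / 2.5% of the
*whole* active population — the marginals are recovered at n = 20,000
within binomial tolerance (≈ 3·√(p(1−p)/n), about 1 percentage point).
What the generator does **not** model: correlation between medication
burden and utilization (an open knob left at independence), refill
adherence and longitudinal dynamics, diagnosis codes, seasonal effects,
and missing demographics. Passing tests therefore demonstrate pipeline
correctness and calibration recovery, not fidelity to any real claims
population — cohort sizes, mean PIPs and cost comparisons on synthetic
data are illustrative only.

## Numerical and testing choices

Frequency sums are checked to 1e-9; PIP oracle equivalence to 1e-12
before rounding; rounding is half-away-from-zero (so 0.275 → 28). The
Welch statistic is cross-checked against exact permutation enumeration
with mid-p tie handling (the discrete permutation distribution at n = 5+5
puts ~20% of its mass exactly at the observed |t|), and the proportion
z-test against Fisher's exact test for order-of-magnitude and
significance agreement. Default problem sizes — 5,000 patients for the
end-to-end study, 20,000 for calibration checks, 200 random small
knowledge bases for oracle equivalence — run the full suite in well
under a minute while keeping binomial tolerances tight.

## Known limitations

- Fixture phenotype frequencies and actionable sets are plausible
  stand-ins, not curated CPIC content; real deployments must supply
  their own knowledge base.
- The PIP reconstruction assumes cross-gene independence and a
  particular phenoconversion ladder semantics; vendors' proprietary
  scores may weight severity or gene interactions differently.
- The DDI table is intentionally tiny; absolute DDI burdens on
  synthetic data are far below what a production interaction engine
  reports.
- Eligibility uses age at window start and ingredient-level identity;
  claims adjudication subtleties (reversals, eligibility spans) are
  ignored.
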