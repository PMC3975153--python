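# Methods

## Model and assumptions

`intersamm` treats a woman's reported pregnancy/delivery indicators as
evidence in two parallel Bayesian updates, run per case over the
affirmative responses only.

**All-cause track.** The hypothesis "this delivery involved severe acute
maternal morbidity" (S) is updated against its complement in odds form:
each affirmative indicator I multiplies the odds by the likelihood ratio
P(I|S)/P(I|¬S). The matrix stores P(I) and P(I|S); P(I|¬S) is derived by
total probability, P(I|¬S) = (P(I) − P(I|S)·P(S))/(1 − P(S)), and clamped
to [1e−6, 1−1e−6] with a warning if the stored values are incoherent.

**Cause track.** A categorical posterior over the 10 substantive cause
categories starts at the normalized unconditional priors P(C)/ΣP(C) and
is multiplied by P(I|C) per affirmative indicator, renormalized to sum
to 1. The residual "uncomplicated" mass (1 − ΣP(C)) is deliberately kept
*outside* this normalization: whether a case is morbid at all is the
all-cause track's job, and keeping the tracks separate lets the morbidity
likelihood and the cause mix disagree, which is exactly what the
classification layer exploits.

Assumptions worth stating plainly:

* indicators are conditionally independent given the hypothesis (the
  usual naive-Bayes assumption; correlated symptom clusters will
  over-count evidence);
* only affirmative responses are evidence. An explicit "no" and a missing
  answer are treated identically, because survey instruments differ in
  which indicators they ask at all, and absence of a lay report is weak
  evidence at best;
* updates commute (a product of likelihood ratios), so the result is
  independent of processing order. The engine nevertheless fixes
  processing to registry order and accumulates in log space with a single
  final exponentiation/normalization per track — this makes even the
  floating-point rounding order-independent and prevents underflow at the
  20+ indicators real cases can reach.

## Classification rules

* **Status cutoffs** (`low_cut=0.30`, `high_cut=0.90` on the morbidity
  likelihood): below 0.30 the case is uncomplicated and its cause
  probabilities are zeroed; above 0.90 it is a SAMM (near-miss) case;
  between the cutoffs it is morbid non-SAMM. Both boundaries are
  inclusive to the middle band ("below 30%" and "in excess of 90%" read
  as strict inequalities).
* **Determinacy**: a cause is reportable iff its posterior likelihood
  reached √P(C). The wording "increased by … the square root of the
  unconditional cause probability" admits a second reading (posterior ≥
  P(C) + √P(C)); we default to "increased **to** √P(C)" because √p > p
  already forces a genuine increase for p < 1, while the additive reading
  is unsatisfiable for priors above ≈0.38. Both are available through
  `RuleConfig.determinacy_rule` (`to_sqrt` / `by_sqrt`).
* **Multiple causes**: causes sorted descending (ties broken by registry
  order); each further cause is kept iff it is within 50% of the
  *previously kept* cause, stopping at the first failure, so the kept set
  is a prefix. `RuleConfig.chain_reference="top"` switches the reference
  to the leading cause for sensitivity analysis.
* A morbid case with no determinate cause is *indeterminate* and carries
  its whole unit mass into the indeterminate channel at aggregation; for
  cause-assigned cases the remainder 1 − Σ(assigned likelihoods) is the
  per-case uncertainty mass.

## Aggregation

Population counts are accumulated by fractional case-splitting and
divided by the cohort size, so the summary conserves mass exactly:
uncomplicated + non-scope + indeterminate + uncertainty + Σ CSMF = 1.
Two scopes mirror the two ways cause burden is usually reported:
`samm_only` attributes causes for >90% cases only (other morbid cases
appear as a separate non-scope bucket) and `all_morbid` attributes causes
for everything above the 30% cutoff. Fractions are kept at full float
precision; percentage rounding (1 d.p.) happens only in
`PopulationSummary.to_table`.

`evaluation.aggregate_causes` merges CSMFs into broad aetiological
categories; the default scheme is PIH = pre-eclampsia ∪ eclampsia,
Dystocia = uterine rupture/pre-rupture ∪ obstructed labour, Haemorrhage =
antepartum ∪ postpartum, Infection = puerperal infection ∪ malaria ∪
other infections, with anaemia standalone.

## Reference comparisons

Categorical references (clinician reviews, simulation truth) carry no
likelihoods, so each reference case's unit mass is split *evenly* among
its mapped causes; any uncertainty the reviewer felt is unrecoverable, so
reference summaries have a zero uncertainty bucket, and CSMF difference
reports (`compare_csmf`: per-cause absolute differences with mean, min,
max) are computed over the determinate causes only. Cause terminologies
are reconciled through an explicit `CauseMap` (foreign label → registry
code or the `other` sink); unmapped labels are an error rather than a
silent drop, keeping the reconciliation auditable. Status agreement is
reported as a column-normalized cross-tab against 3-level references or
2-level (morbid / non-morbid) ones, collapsing via
morbid = morbid_non_samm ∪ samm.

## The default matrix

No validated prior matrix exists publicly, so the packaged 72×10 matrix
is **illustrative** and labelled as such in its file header. It is
generated by `scripts/build_default_matrix.py`: each cause has a set of
clinically motivated indicator grades on the quantized scale
{I≈1, A=0.5, B=0.1, C=0.02, D=0.005, E=0.001}; every ungraded
(indicator, cause) cell is floored to the largest grade not exceeding
that indicator's baseline reporting rate among uncomplicated women, so
unrelated indicators mildly argue *against* morbidity rather than
spuriously for it. P(I|SAMM) is the cause-prior-weighted mixture of the
P(I|C) row and P(I) is rebuilt by total probability (P(SAMM)=0.05,
ΣP(C)=0.079), which makes the file internally coherent: the derived
P(I|¬S) recovers the authored baselines exactly. The exact grade values
of the original expert-elicitation scale are not published; this scale is
a stand-in, and all quantitative validation in the test suite uses
synthetic matrices, never this file.

## Synthetic cohorts

The generator draws, per case: a true status from configurable
prevalences; for morbid cases a single true cause from a configurable
CSMF; latent indicator presence Bernoulli(P(I|C)) (morbid) or
Bernoulli(P(I|¬S)) (uncomplicated) under the generating matrix; and the
observed response by independent per-indicator misclassification with
`report_sensitivity` (default 0.9) and `report_false_positive` (default
0.02). Defaults emulate a hospital-based development case-mix — about two
uncomplicated deliveries per complicated one (`prevalence_samm=0.33`,
`prevalence_morbid_non_samm=0`) — and the false-positive rate yields
roughly one spurious affirmative per uncomplicated woman over a 25–72
indicator instrument, matching the reporting behaviour such surveys see
in practice. All randomness flows from one named seeded generator.

What the generator does **not** emulate: correlated recall bias across
indicators, multi-cause truth (single-cause truth keeps recovery studies
interpretable; the multi-cause reporting rules are still exercised
because posteriors spread naturally), instrument-specific missingness,
and severity gradations within "morbid". Passing recovery tests
therefore show the pipeline inverts its own generative assumptions under
independent reporting noise — not that it is calibrated for any real
population.

`perturb_matrix` jitters the conditionals on the log-odds scale,
expit(logit(p) + sd·z) with z ~ N(0,1) drawn from the seed alone, so a
grid of sd values shares one noise realization and the induced
perturbation grows continuously with sd.

## Study sizes and numerical choices

The recovery study uses a well-separated synthetic matrix (5 causes × 5
disjoint signature indicators at P(I|C)=0.8, baseline 0.02, P(SAMM)=0.05,
cause priors 0.02) with a 5000-case cohort, true CSMF
(0.30, 0.25, 0.20, 0.15, 0.10), sensitivity 0.9 and false-positive 0.02,
reported under `samm_only` scope and compared on the conditional
(sums-to-one) CSMF scale, since a generating CSMF is defined among morbid
cases only. The robustness study reuses one 2000-case cohort across
perturbation scales sd ∈ {0, 0.1, 0.2, 0.4}. These sizes give
comfortably sub-percent Monte-Carlo noise while keeping the whole suite
fast.

Other numerical conventions: probabilities are validated to the open
interval (0,1); derived P(I|¬S) clamps to [1e−6, 1−1e−6] with a warning;
equal cause likelihoods are ordered by registry position for
deterministic output; and an underflow of the entire cause vector (only
possible with externally supplied degenerate vectors, since matrix
validation forbids zero conditionals) raises rather than renormalizing
garbage.

## Known limitations

* Conditional independence over-counts clustered symptoms (e.g. the
  fever items); a correlation-aware likelihood is future work.
* With affirmative-only updating, a case reporting nothing sits at the
  prior, so P(SAMM) must lie below `low_cut` for "uncomplicated" to be
  reachable at all.
* The bundled matrix is a plausibility artefact; population estimates
  from it should not be quoted as evidence about any real setting.
* CSMFs are point estimates; no sampling variance or interval is
  attached (a bootstrap over cases would be the natural extension).
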