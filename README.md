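# intersamm

Probabilistic estimation of the population burden and causes of **severe
acute maternal morbidity (SAMM)** — life-threatening obstetric
complications that the woman survives ("near-misses") — from women's own
reports of their pregnancy and delivery experiences.

In settings where many women deliver at home, the only scalable source of
morbidity data is the retrospective interview, and lay reports of signs
and symptoms are noisy and unspecific. Forcing each woman's history into
a binary "complicated / uncomplicated" verdict discards that uncertainty
and tends to overestimate burden. `intersamm` instead carries the
uncertainty through: every reported indicator shifts the *likelihood* of
severe morbidity and of each candidate cause, and cases are aggregated
fractionally so that the population totals retain an explicit measure of
diagnostic uncertainty. The intended output is population-level — cause
distributions for priority-setting and evaluation — not individual
diagnosis.

## The model

The model is parameterised by prior probabilities authored on a quantized
semi-qualitative scale: P(SAMM), the unconditional probabilities P(C) of
10 direct/indirect cause categories (puerperal infection, antepartum and
postpartum haemorrhage, pre-eclampsia, eclampsia, obstructed labour,
uterine rupture/pre-rupture, anaemia, malaria, other infections), the
baseline reporting probability P(I) of each of 72 indicators, and the
conditionals P(I|C) and P(I|SAMM).

For each case, two Bayesian tracks run over the affirmative indicators
(indicators are assumed conditionally independent given the hypothesis;
"no" and "missing" responses carry no evidence):

* **all-cause track** — a two-hypothesis odds update,
  `odds' = odds × P(I|S)/P(I|¬S)`, with
  `P(I|¬S) = (P(I) − P(I|S)·P(S)) / (1 − P(S))`;
* **cause track** — a categorical posterior over the 10 causes,
  `P'(c) ∝ P(c) × P(I|c)`, renormalized after each indicator.

Posteriors are then classified: below 30% morbidity likelihood a case is
uncomplicated (cause probabilities zeroed); above 90% it is a SAMM case;
in between it is morbid but not near-miss. A cause is reportable
("determinate") only if its posterior reached √P(C); multiple causes are
reported while each falls within 50% of the previously kept one; cases
with no determinate cause are "indeterminate". Finally each morbid case
is split fractionally — its cause likelihoods go to the cause counts and
the remainder to a *cause uncertainty* count — and dividing by the number
of cases yields cause-specific morbidity fractions (CSMFs).

No validated probability matrix ships with the package: the bundled
72×10 matrix is **illustrative**, authored from clinical plausibility on
the scale `{I≈1, A=0.5, B=0.1, C=0.02, D=0.005, E=0.001}`, and is meant
as a structural template for locally elicited priors.

## Worked example

Simulate a cohort with known truth from the bundled matrix, score it, and
summarize (the same pipeline is available as the `intersamm`
`simulate` / `run` / `evaluate` / `validate-matrix` subcommands):

```python
import intersamm as im

matrix = im.default_matrix()                      # 72 indicators x 10 causes
config = im.SimulationConfig(generating_matrix=matrix, n_cases=1000, seed=42)
cases, truths = im.simulate_cohort(config)

profiles = im.evaluate_cohort(cases, matrix)      # per-case posteriors
classes = im.classify_cohort(profiles, matrix)    # statuses + causes
summary = im.summarize(classes, scope="all_morbid",
                       cause_codes=matrix.causes.codes)
print(summary.to_table().to_string(index=False))
```

```
              category  percent
Non-scope morbid cases      0.0
         Uncomplicated     80.0
     Cause uncertainty      2.2
   puerperal_infection      4.2
postpartum_haemorrhage      3.0
       uterine_rupture      1.7
               malaria      1.7
             eclampsia      1.6
          preeclampsia      1.6
     obstructed_labour      1.5
               anaemia      1.4
antepartum_haemorrhage      0.7
       other_infection      0.4
           Other cause      0.0
   Indeterminate cause      0.0
```

Each row is a fraction of all 1000 deliveries: 80.0% were classified
uncomplicated, the cause rows are CSMFs after fractional splitting, and
"Cause uncertainty" (2.2%) is the case mass the method declined to
attribute to any cause. One simulated near-miss in this cohort
(`sim0019`, truly a postpartum haemorrhage) reported 8 indicators,
reached a SAMM likelihood of 0.959 and was assigned
`postpartum_haemorrhage` at likelihood 0.999, leaving 0.001 of its mass
to uncertainty.

Evaluation utilities compare such summaries with categorical reference
classifications (clinician review or simulation truth): even splitting of
multi-cause references, per-cause absolute-difference reports,
column-normalized status cross-tabs, and aggregation into broad
categories (PIH, dystocia, haemorrhage, infection, anaemia).

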