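# kbcdss

Knowledge-based clinical decision support for psychiatric nursing diagnoses,
with the evaluation machinery to measure whether such support actually
improves diagnostic decision-making.

Standardized nursing-diagnosis taxonomies describe each diagnosis through
*defining characteristics* (observable evidence), *related factors*, and — for
risk-type diagnoses — *risk factors*. A knowledge-based clinical decision
support system (KBCDSS) links these elements to structured patient-assessment
items through scored *indicators* and, given a patient's positive findings,
suggests the evidence elements and diagnoses they support. This package
implements the two classic inference engines for building those indicators,
the guidance generator, the diagnostic-competency evaluator used in pre/post
intervention studies of such systems, the accompanying statistical battery,
and a seeded synthetic-data generator so the whole pipeline is exercisable
without any clinical data.

It is intended for informatics researchers and educators who want to study or
teach decision-support evaluation, not for clinical use.

## The two inference engines

**Clinical Diagnostic Validity (CDV, Fehring's model).** Two nurses — one
junior, one senior — assess the same patients. For each
(assessment item, diagnosis, element) association the engine computes the
weighted interrater reliability ratio

    R = [(F1/N + F2/N) / 2] × [A / (A + D)]

where F1 and F2 are the raters' positive-observation frequencies, N the number
of patients observed, and A/D the agreement/disagreement counts. Associations
with R ≥ 0.80 are *major* indicators, 0.50 ≤ R < 0.80 *minor*; lower scores
are retained but never displayed as guidance.

**Bayesian decision model.** From a patient co-occurrence registry the engine
estimates P(+|DC), P(DC) and P(+|Non_DC) by relative frequency and scores each
association with the posterior probability that the element is present given a
positive finding:

    P(DC|+) = P(+|DC)·P(DC) / [P(+|DC)·P(DC) + P(+|Non_DC)·P(Non_DC)]

## Competency evaluation

Each student care plan is compared against an expert researcher's reference
plan for the same patient-diagnosis, counting taxonomy-valid evidence
elements: an equal count is a true positive, more is a false positive, fewer a
false negative — the three outcomes partition the participants. Over a study
arm, PPV = TP/(TP+FP) and sensitivity = TP/(TP+FN). A plan is *compliant* when
it cites at least 3 valid defining characteristics or risk factors.

The statistics module recomputes every test such studies report from first
principles: Pearson chi-square (no continuity correction), McNemar–Bowker
symmetry, one-way ANOVA from (n, mean, SD) summaries, one-covariate ANCOVA
(Type III group F), Scheffé post hoc comparisons, and noncentral-F
power/sample-size analysis with dropout inflation.

## Worked example

```python
import kbcdss as k

cfg = k.SimulationConfig(seed=1)              # 22 diagnoses, 5 aspects, 3 arms
kb = k.generate_mock_kb(cfg)

# build a CDV indicator table from simulated paired-rater observations
obs = k.simulate_rater_observations(kb, cfg)
table = k.build_cdv_indicators(obs, kb)

# evaluate a simulated three-arm pre/post cohort
plans = k.simulate_cohort(kb, cfg)
comp, _ = k.evaluate_care_plans(plans, kb)
print(comp.row("cdv", "posttest").to_dict())
```

prints

```
{'group': 'cdv', 'phase': 'posttest', 'n': 203, 'tp': 131, 'fp': 9, 'fn': 63,
 'compliant': 164, 'compliance_pct': 80.79, 'ppv': 0.94, 'sensitivity': 0.68}
```

i.e. in the simulated CDV arm at posttest, 131 of 203 students matched the
expert's evidence count exactly, giving PPV 0.94 and sensitivity 0.68, with
80.79% of plans citing at least three valid defining characteristics.

The same pipeline is available from the shell:

```
kbcdss simulate --seed 1 --out-dir runs/demo
kbcdss build-kb --kb runs/demo/kb.json --engine cdv \
    --observations runs/demo/observations.csv --out runs/demo/kb_cdv.json
kbcdss evaluate --kb runs/demo/kb.json --plans runs/demo/plans.csv \
    --out runs/demo/competency.json
kbcdss reproduce          # recompute the published count tables and diff
kbcdss stats power --f 0.2 --alpha 0.05 --power 0.99 --groups 3 \
    --covariates 1 --dropout 0.15
```

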