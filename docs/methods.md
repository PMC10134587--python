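# Methods

## Knowledge-base model

A knowledge base holds diagnoses (actual or risk type), their elements
(defining characteristics, related factors, risk factors), and assessment
items classified into the five aspects of a whole-person psychiatric nursing
assessment (physical, psychological, intellectual, social, spiritual). The
shipped taxonomy is entirely mock content with neutral `DX-001…` codes: the
real standardized taxonomy is copyrighted, and a generated one is both
license-clean and controllable in tests. Identifiers are case-sensitive
exact-match strings to avoid locale-dependent folding.

Care-plan records keep out-of-taxonomy element ids rather than rejecting
them, flagged invalid: the competency evaluator must see them as
non-compliant evidence, and silent drops would bias counts.

Structural validation returns violations as data (a list of named rule
breaches) rather than raising, so a whole artifact can be audited in one
pass; schema errors during deserialization, in contrast, raise with the JSON
pointer of the first offending node.

## CDV engine

The weighted interrater reliability ratio
`R = [(F1/N + F2/N)/2] · [A/(A+D)]` is computed per association from paired
junior/senior observations. Two conventions are ambiguous in the model's
verbal description and are explicit parameters here:

- `agreement_mode` — what counts as an agreement. Default `both_states`
  (both raters coincide on presence *or* absence), the usual
  interrater-reliability convention; `presence_only` counts only joint
  presence. Note that some published tallies (e.g. F1=8, F2=9, N=10 with
  A=8) are only realizable under `presence_only`.
- N is per-association (patients for whom the association was observed), not
  global; callers controlling the observation stream control N.

Display bands: R ≥ 0.80 major, 0.50 ≤ R < 0.80 minor (both boundaries
inclusive at the bottom of their band), R < 0.50 excluded. Excluded entries
stay in the table — builds must be reproducible — but are never emitted as
guidance. Scores are kept at full float precision; only display rounds to
2 decimals (half-up, matching how such tables are printed).

## Bayesian engine

The posterior `P(DC|+) = P(+|DC)P(DC) / [P(+|DC)P(DC) + P(+|Non_DC)P(Non_DC)]`
is computed from relative-frequency estimates of the three probabilities on a
per-association 2×2 co-occurrence registry. Estimation choices:

- Optional symmetric pseudo-count smoothing (default 0). With smoothing 0 an
  empty DC or non-DC margin is an explicit error rather than a silent 0/0.
- Display thresholds reuse the CDV bands (0.80/0.50) for parity between the
  two engines; no separate thresholds are published for Bayesian indicators.
- Three association families (assessment item → defining characteristic,
  defining characteristic → related factor, assessment item → risk factor)
  share one registry schema and one code path; for the second family the
  first association slot holds a defining characteristic of the same
  diagnosis.

With zero smoothing the count-based posterior reduces algebraically to
"fraction of assessment-positive patients who have the element", which the
tests exploit as a brute-force patient-enumeration oracle.

## Guidance

For each positive finding the displayable indicator entries are collected,
grouped by diagnosis, deduplicated per element keeping the maximum score
(strongest evidence wins), and diagnoses ranked by (count of distinct major
elements, sum of scores, diagnosis code). The ranking key is this package's
own convention — no ordering is published — chosen so major-level evidence
dominates and ties break deterministically. A control-arm null engine
(`unguided_element_list`) returns unscored taxonomy-order element lists,
emulating a care-planning system without guidance.

The ≥3-element support rule counts distinct taxonomy-valid evidence elements
(defining characteristics for actual diagnoses, risk factors for risk
diagnoses); related factors and flagged-invalid ids never count.

## Competency evaluation

Classification compares *counts* of valid elements between student and
researcher (equal → TP, more → FP, fewer → FN), which makes the three
outcomes an exact partition of participants and reproduces published
partition arithmetic. A strict `set` mode (TP requires the identical element
set) is provided because the verbal definition of a true positive can be
read either way; count mode is the default. PPV and sensitivity are computed
over participants per (arm, phase).

## Statistics

- Pearson chi-square: `Σ(O−E)²/E`, margins-based expecteds, no continuity
  correction anywhere — the published between-arm statistics are reproduced
  only without correction. Zero expected cells are errors.
- McNemar–Bowker: `(b−c)²/(b+c)` for 2×2 without continuity correction;
  Bowker's pairwise sum for k×k with df = number of discordant pairs
  (symmetric zero pairs drop a df); all-concordant tables are undefined and
  raise.
- Summary ANOVA: `SSB = Σ nᵢ(mᵢ−m̄)²`, `SSW = Σ(nᵢ−1)sdᵢ²`; identical to
  raw-data ANOVA by the moment identity. Printed means/SDs are treated as
  exact; F values re-derived from 2-decimal summaries carry roughly ±0.5%
  rounding error, which is the comparison band used when diffing against
  printed F values.
- ANCOVA: group F from `outcome ~ covariate + group` with sum-to-zero group
  coding and Type III (partial) sums of squares, df = (k−1, N−k−1); computed
  by comparing full vs covariate-only least-squares fits. Type III is the
  standard choice for unbalanced groups.
- Scheffé: pair (i,j) significant iff
  `(mᵢ−mⱼ)²/(MSW(1/nᵢ+1/nⱼ)) > (k−1)·F_crit(α; k−1, N−k)`; the rendering
  produces a full chain ("a < c < b") when every adjacent pair in mean order
  is significant, otherwise the list of significant pairs.
- Power/sample size: noncentrality λ = f²·N_total, denominator df
  N − k − c, smallest N found by bisection (power is monotone in N). This is
  one of several conventions in circulation; it is documented rather than
  reverse-engineered from any particular published N. Dropout inflation is
  `ceil(n/(1−rate))` per group.
- p-values always come from scipy distribution tails, never lookup tables;
  the display format is 3 decimals with "< .001" below that.

## Synthetic-data generator

The generator emulates the study conditions end to end. Defaults are fixed
once as the generator's study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_diagnoses` | 22 | diagnoses in the mock taxonomy |
| `n_aspects` | 5 (fixed) | assessment framework aspects |
| `n_items_per_aspect` | 6 | 30 assessment items total |
| `n_elements_per_diagnosis` | 6 | ≥3 required (compliance satisfiable) |
| `risk_fraction` | 0.2 | ~4 of 22 diagnoses risk-type |
| `n_patients` | 120 | patients behind observations/registry |
| `rater_agreement` | 0.9 | P(rater reports the latent truth) |
| `element_prevalence` | 0.5 | P(element present per patient) |
| `registry_sensitivity` / `registry_false_positive` | 0.85 / 0.15 | assessment accuracy in the registry |
| `truth_element_rate` | 0.7 | P(evidence element present in a care case) |
| cohort sizes | 206 / 203 / 198 | control / CDV / BADE arms |
| fidelity, pretest | 0.55 all arms | arms start homogeneous |
| fidelity, posttest | 0.57 / 0.88 / 0.75 | control / CDV / BADE |
| over-identification, pretest | 0.22 all arms | spurious-element rate |
| over-identification, posttest | 0.20 / 0.06 / 0.10 | control / CDV / BADE |

Rater noise model: latent truth ~ Bernoulli(prevalence); each rater
independently reports the truth with probability `rater_agreement`. Under
this model E[F/N] = pa + (1−p)(1−a) and the agreement probability is
a² + (1−a)², which gives the closed-form expectation of R the calibration
test checks.

Cohort model: the researcher's plan is the latent truth (each evidence
element present with `truth_element_rate`, at least one guaranteed); the
student keeps each true element with the arm/phase fidelity and adds each
absent valid element at the over-identification rate. One evaluated
diagnosis per participant per phase. Arm effects are *only*
fidelity/over-identification shifts: the generator exercises the evaluator
and the statistics; it does not model the guidance screen cognitively, nor
questionnaire responses. The pretest fidelities were chosen so pretest true
positives land near the 30% the arms start from, and posttest values so the
arm ordering and rough magnitudes of posttest PPV/sensitivity emerge; exact
published posttest proportions are not calibration targets.

Determinism: all randomness flows through `numpy.random.default_rng` seeded
as `[seed, stream]` with a distinct stream per generator; iteration orders
are explicit, so every artifact is byte-reproducible across platforms.

What passing synthetic tests do **not** show: real care plans have
correlated element identification, heterogeneous students, multiple
diagnoses per patient, and researcher error — none of which the generator
models. The synthetic checks validate the arithmetic and calibration of the
pipeline, not clinical realism.

## Problem sizes in the shipped checks

The null-calibration checks use 2000 replicate cohorts of 60 participants
per arm (chi-square) and 2000 replicates of n = 60 (ANCOVA); parameter
recovery uses 200 participants per arm with fidelity held constant across
phases so both phases contribute observations; the between-arm ordering
check averages 200 full-size replicate cohorts. These sizes give Monte-Carlo
standard errors comfortably inside the asserted bands (e.g. ±0.005 on a 0.05
rejection rate at 2000 replicates).

## Known limitations

- The Bayesian engine scores each association independently; there is no
  naïve-Bayes combination across findings.
- The CDV model is defined for exactly one junior/senior rater pair.
- No specificity or NPV: the TP/FP/FN partition defines no true negatives.
- The sample-size routine's convention (λ = f²·N, df₂ = N − k − c) need not
  match every published calculation performed with other tools or test
  families.
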