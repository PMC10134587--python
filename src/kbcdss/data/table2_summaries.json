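{
  "schema_version": 1,
  "description": "Posttest questionnaire quality-dimension scores per study arm: n, mean, SD, the printed one-way ANOVA F, and the printed post hoc ordering (a = control, b = cdv, c = bade).",
  "n": {"control": 206, "cdv": 203, "bade": 198},
  "rows": [
    {"dimension": "information_quality", "control": [2.01, 1.39], "cdv": [2.93, 1.35], "bade": [2.57, 1.38], "printed_f": 23.38, "ordering": "a < c < b"},
    {"dimension": "currency", "control": [2.06, 1.35], "cdv": [2.87, 1.31], "bade": [2.51, 1.37], "printed_f": 18.81, "ordering": "a < c < b"},
    {"dimension": "completeness", "control": [2.22, 1.40], "cdv": [3.04, 1.32], "bade": [2.78, 1.26], "printed_f": 20.65, "ordering": "a < b; a < c"},
    {"dimension": "accuracy", "control": [1.19, 1.33], "cdv": [2.57, 1.34], "bade": [2.23, 1.24], "printed_f": 18.66, "ordering": "a < c < b"},
    {"dimension": "format", "control": [2.22, 1.41], "cdv": [3.09, 1.32], "bade": [2.75, 1.28], "printed_f": 22.04, "ordering": "a < c < b"},
    {"dimension": "system_quality", "control": [2.05, 1.47], "cdv": [3.07, 1.37], "bade": [2.64, 1.42], "printed_f": 26.47, "ordering": "a < c < b"},
    {"dimension": "reliability", "control": [2.01, 1.33], "cdv": [2.95, 1.38], "bade": [2.53, 1.42], "printed_f": 23.67, "ordering": "a < c < b"},
    {"dimension": "accessibility", "control": [1.79, 1.51], "cdv": [2.57, 1.34], "bade": [2.23, 1.24], "printed_f": 18.66, "ordering": "a < c < b"},
    {"dimension": "flexibility", "control": [2.01, 1.36], "cdv": [3.02, 1.33], "bade": [2.63, 1.33], "printed_f": 29.97, "ordering": "a < c < b"},
    {"dimension": "timeliness", "control": [1.86, 1.31], "cdv": [3.06, 1.21], "bade": [2.66, 1.25], "printed_f": 48.35, "ordering": "a < c < b"},
    {"dimension": "service_quality", "control": [2.03, 1.50], "cdv": [3.02, 1.41], "bade": [2.74, 1.34], "printed_f": 26.42, "ordering": "a < b; a < c"},
    {"dimension": "responsiveness", "control": [2.02, 1.42], "cdv": [2.99, 1.34], "bade": [2.64, 1.48], "printed_f": 24.51, "ordering": "a < c < b"},
    {"dimension": "empathy", "control": [1.97, 1.41], "cdv": [2.97, 1.37], "bade": [2.63, 1.34], "printed_f": 28.71, "ordering": "a < c < b"},
    {"dimension": "service_reliability", "control": [2.20, 1.39], "cdv": [3.11, 1.28], "bade": [2.66, 1.38], "printed_f": 23.08, "ordering": "a < c < b"},
    {"dimension": "tangibles", "control": [1.96, 1.36], "cdv": [2.87, 1.34], "bade": [2.73, 1.34], "printed_f": 27.17, "ordering": "a < b; a < c"},
    {"dimension": "assurance", "control": [1.93, 1.43], "cdv": [3.17, 1.29], "bade": [2.71, 1.38], "printed_f": 42.14, "ordering": "a < c < b"},
    {"dimension": "user_satisfaction", "control": [2.04, 1.54], "cdv": [3.00, 1.39], "bade": [2.60, 1.37], "printed_f": 24.15, "ordering": "a < c < b"},
    {"dimension": "perceived_enjoyment", "control": [1.80, 1.36], "cdv": [2.94, 1.36], "bade": [2.61, 1.33], "printed_f": 38.55, "ordering": "a < c < b"},
    {"dimension": "perceived_ease_of_use", "control": [1.03, 1.36], "cdv": [2.80, 1.27], "bade": [2.47, 1.27], "printed_f": 107.64, "ordering": "a < c < b"},
    {"dimension": "perceived_usefulness", "control": [1.31, 1.35], "cdv": [3.03, 1.22], "bade": [2.60, 1.23], "printed_f": 101.71, "ordering": "a < c < b"},
    {"dimension": "behavioral_attitude", "control": [2.24, 1.36], "cdv": [3.18, 1.29], "bade": [2.76, 1.22], "printed_f": 27.06, "ordering": "a < c < b"},
    {"dimension": "intention", "control": [2.36, 1.51], "cdv": [3.33, 1.35], "bade": [2.88, 1.38], "printed_f": 24.05, "ordering": "a < c < b"}
  ]
}
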