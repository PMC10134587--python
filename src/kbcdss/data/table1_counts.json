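{
  "schema_version": 1,
  "phase": "pretest",
  "groups": ["control", "cdv", "bade"],
  "n": {"control": 206, "cdv": 203, "bade": 198},
  "counts": {
    "compliance": {"control": 144, "cdv": 152, "bade": 142},
    "false_positive": {"control": 44, "cdv": 47, "bade": 37},
    "false_negative": {"control": 104, "cdv": 95, "bade": 106},
    "true_positive": {"control": 58, "cdv": 61, "bade": 55}
  },
  "printed": {
    "ppv": {"total": 0.58, "control": 0.57, "cdv": 0.56, "bade": 0.60},
    "sensitivity": {"total": 0.36, "control": 0.36, "cdv": 0.39, "bade": 0.34},
    "chi_square": {
      "compliance": 1.29,
      "false_positive": 1.22,
      "false_negative": 1.83,
      "true_positive": 0.29
    },
    "percentages": {
      "compliance": {"control": 69.90, "cdv": 74.88, "bade": 71.72},
      "false_positive": {"control": 21.36, "cdv": 23.15, "bade": 18.69},
      "false_negative": {"control": 50.49, "cdv": 46.80, "bade": 53.54},
      "true_positive": {"control": 28.16, "cdv": 30.05, "bade": 27.78}
    }
  },
  "age_summary": {
    "control": [206, 21.30, 1.44],
    "cdv": [203, 21.59, 1.49],
    "bade": [198, 21.53, 2.00]
  },
  "printed_age_f": 1.74
}
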