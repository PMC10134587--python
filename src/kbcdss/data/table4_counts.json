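{
  "schema_version": 1,
  "phase": "posttest",
  "groups": ["control", "cdv", "bade"],
  "n": {"control": 206, "cdv": 203, "bade": 198},
  "counts": {
    "compliance": {"control": 155, "cdv": 191, "bade": 172},
    "false_positive": {"control": 37, "cdv": 17, "bade": 24},
    "false_negative": {"control": 106, "cdv": 60, "bade": 76},
    "true_positive": {"control": 63, "cdv": 126, "bade": 98}
  },
  "printed": {
    "ppv": {"control": 0.63, "cdv": 0.88, "bade": 0.80},
    "sensitivity": {"control": 0.37, "cdv": 0.68, "bade": 0.56},
    "chi_square": {
      "compliance": 29.57,
      "false_positive": 8.53,
      "false_negative": 20.72,
      "true_positive": 41.24
    },
    "percentages": {
      "compliance": {"control": 75.24, "cdv": 94.09, "bade": 86.87},
      "false_positive": {"control": 17.96, "cdv": 8.37, "bade": 12.12},
      "false_negative": {"control": 51.46, "cdv": 29.56, "bade": 38.38},
      "true_positive": {"control": 30.58, "cdv": 62.07, "bade": 49.49}
    }
  }
}
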