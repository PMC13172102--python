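{
  "group_sizes": {"lvi_pos": 30, "lvi_neg": 54},
  "emvi_prevalence": {"lvi_pos": 0.7, "lvi_neg": 0.24074074074074073},
  "features": {
    "adc_pgse": {
      "lvi_pos": {"kind": "normal", "mean": 1.273, "sd": 0.317},
      "lvi_neg": {"kind": "normal", "mean": 1.497, "sd": 0.401}
    },
    "adc_25hz": {
      "lvi_pos": {"kind": "normal", "mean": 1.583, "sd": 0.42},
      "lvi_neg": {"kind": "normal", "mean": 1.688, "sd": 0.455}
    },
    "adc_40hz": {
      "lvi_pos": {"kind": "lognormal_iqr", "median": 1.45, "q1": 1.167, "q3": 1.681},
      "lvi_neg": {"kind": "lognormal_iqr", "median": 1.664, "q1": 1.39, "q3": 1.977}
    },
    "relative_adc_25hz": {
      "lvi_pos": {"kind": "lognormal_iqr", "median": 0.247, "q1": 0.129, "q3": 0.333},
      "lvi_neg": {"kind": "lognormal_iqr", "median": 0.14, "q1": 0.067, "q3": 0.202}
    },
    "relative_adc_40hz": {
      "lvi_pos": {"kind": "lognormal_iqr", "median": 0.309, "q1": 0.107, "q3": 0.514},
      "lvi_neg": {"kind": "lognormal_iqr", "median": 0.212, "q1": 0.105, "q3": 0.352}
    },
    "ratio_25_40": {
      "lvi_pos": {"kind": "lognormal_iqr", "median": 1.037, "q1": 0.83, "q3": 1.404},
      "lvi_neg": {"kind": "lognormal_iqr", "median": 0.967, "q1": 0.828, "q3": 1.353}
    },
    "ratio_25_pgse": {
      "lvi_pos": {"kind": "lognormal_iqr", "median": 1.247, "q1": 1.129, "q3": 1.333},
      "lvi_neg": {"kind": "lognormal_iqr", "median": 1.134, "q1": 1.045, "q3": 1.198}
    },
    "ratio_40_pgse": {
      "lvi_pos": {"kind": "lognormal_iqr", "median": 1.138, "q1": 0.887, "q3": 1.514},
      "lvi_neg": {"kind": "lognormal_iqr", "median": 1.116, "q1": 0.891, "q3": 1.307}
    },
    "icvf": {
      "lvi_pos": {"kind": "lognormal_iqr", "median": 0.334, "q1": 0.282, "q3": 0.382},
      "lvi_neg": {"kind": "lognormal_iqr", "median": 0.212, "q1": 0.145, "q3": 0.261}
    },
    "d_ex": {
      "lvi_pos": {"kind": "lognormal_iqr", "median": 2.341, "q1": 2.12, "q3": 2.611},
      "lvi_neg": {"kind": "lognormal_iqr", "median": 2.425, "q1": 2.079, "q3": 2.561}
    },
    "cell_diameter": {
      "lvi_pos": {"kind": "lognormal_iqr", "median": 12.808, "q1": 11.133, "q3": 15.195},
      "lvi_neg": {"kind": "lognormal_iqr", "median": 11.812, "q1": 10.6, "q3": 13.293}
    },
    "cellularity": {
      "lvi_pos": {"kind": "lognormal_iqr", "median": 2.861, "q1": 2.443, "q3": 3.313},
      "lvi_neg": {"kind": "lognormal_iqr", "median": 1.964, "q1": 1.375, "q3": 2.579}
    },
    "tumor_length": {
      "lvi_pos": {"kind": "normal", "mean": 5.34, "sd": 1.99},
      "lvi_neg": {"kind": "normal", "mean": 5.26, "sd": 2.13}
    }
  },
  "correlations": [
    ["icvf", "cellularity", 0.8],
    ["icvf", "adc_pgse", -0.5]
  ]
}
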