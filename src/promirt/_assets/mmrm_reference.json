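{
  "description": "Published mean (95% CI) change from baseline in RS-Total over 4-week intervals for the FULFIL trial, from the MMRM analysis and from the item-based model simulations. Used as the packaged comparator table.",
  "interval_labels": ["1-4", "5-8", "9-12", "13-16", "17-20", "21-24"],
  "arms": {
    "FF/UMEC/VI": {
      "mmrm": {
        "mean": [-1.45, -2.00, -2.23, -2.42, -2.43, -2.31],
        "lo":   [-1.66, -2.25, -2.51, -2.73, -2.74, -2.62],
        "hi":   [-1.24, -1.75, -1.95, -2.11, -2.12, -2.00],
        "se":   [0.11, 0.13, 0.14, 0.15, 0.16, 0.16]
      },
      "irt": {
        "mean": [-1.33, -1.81, -2.17, -2.35, -2.43, -2.47],
        "lo":   [-1.44, -1.93, -2.30, -2.49, -2.57, -2.61],
        "hi":   [-1.22, -1.67, -2.02, -2.18, -2.26, -2.30],
        "se":   [0.06, 0.07, 0.07, 0.08, 0.08, 0.08]
      }
    },
    "BUD/FOR": {
      "mmrm": {
        "mean": [-0.50, -0.77, -1.05, -1.09, -1.02, -0.96],
        "lo":   [-0.71, -1.02, -1.33, -1.39, -1.33, -1.27],
        "hi":   [-0.29, -0.52, -0.77, -0.79, -0.71, -0.64],
        "se":   [0.11, 0.13, 0.14, 0.15, 0.16, 0.16]
      },
      "irt": {
        "mean": [-0.37, -0.65, -0.84, -0.92, -0.96, -0.97],
        "lo":   [-0.45, -0.74, -0.95, -1.04, -1.08, -1.10],
        "hi":   [-0.28, -0.53, -0.69, -0.77, -0.80, -0.81],
        "se":   [0.04, 0.05, 0.07, 0.07, 0.07, 0.07]
      }
    }
  }
}
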