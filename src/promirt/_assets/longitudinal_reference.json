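{
  "description": "Published longitudinal latent-trajectory model estimates for the FULFIL trial (Weibull disease-progression plus offset drug effect on the latent symptom scale). RSEs for variance and residual rows are on the approximate standard-deviation scale. Used as generating values for synthetic trials and for precision summaries.",
  "arms": {
    "FF/UMEC/VI": {
      "theta0": {"value": 0.33, "rse": 0.23},
      "t_prog": {"value": 0.08, "rse": 0.03},
      "r_max": {"value": -0.31, "rse": 0.11},
      "gamma": {"value": 9.27, "rse": 0.13},
      "offset": {"value": -0.27, "rse": 0.08},
      "omega2_theta0": {"value": 1.09, "rse": 0.03},
      "omega2_t_prog": {"value": 0.45, "rse": 0.03},
      "omega2_r_max": {"value": 0.89, "rse": 0.04},
      "omega2_offset": {"value": 0.37, "rse": 0.05},
      "corr": [
        {"pair": ["r_max", "offset"], "value": 0.11, "rse": 0.24},
        {"pair": ["theta0", "offset"], "value": -0.12, "rse": 0.20}
      ]
    },
    "BUD/FOR": {
      "theta0": {"value": 0.29, "rse": 0.28},
      "t_prog": {"value": 0.08, "rse": 0.03},
      "r_max": {"value": -0.16, "rse": 0.25},
      "gamma": {"value": 16.9, "rse": 0.75},
      "offset": {"value": -0.08, "rse": 0.30},
      "omega2_theta0": {"value": 1.47, "rse": 0.03},
      "omega2_t_prog": {"value": 0.46, "rse": 0.03},
      "omega2_r_max": {"value": 0.98, "rse": 0.06},
      "omega2_offset": {"value": 0.42, "rse": 0.05},
      "corr": [
        {"pair": ["theta0", "offset"], "value": -0.10, "rse": 0.27},
        {"pair": ["r_max", "theta0"], "value": -0.13, "rse": 0.17}
      ]
    }
  },
  "shared": {
    "sigma2": {"value": 0.32, "rse": 0.02},
    "smoking": {"value": 0.13, "rse": 0.62},
    "region": {
      "1": {"value": -0.64, "rse": 0.13},
      "2": {"value": 0.0, "rse": null},
      "3": {"value": -0.61, "rse": 0.13},
      "4": {"value": -0.20, "rse": 0.40},
      "5": {"value": -0.41, "rse": 0.27},
      "6": {"value": -0.98, "rse": 0.12}
    }
  },
  "design": {
    "n_per_arm": {"FF/UMEC/VI": 907, "BUD/FOR": 894},
    "smoker_fraction": 0.44,
    "region_fractions": {"1": 0.21, "2": 0.24, "3": 0.21, "4": 0.18, "5": 0.06, "6": 0.10},
    "baseline_rs_total": {"FF/UMEC/VI": {"mean": 12.2, "sd": 5.85}, "BUD/FOR": {"mean": 12.9, "sd": 5.96}}
  }
}
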