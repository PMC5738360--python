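{
  "seed": 1,
  "outdir": "runs/demo",
  "log_level": "INFO",
  "noise": {"kind": "multiplicative-lognormal", "cv_or_sd": 0.1},
  "grid": {
    "truth": {"G_max": 1000.0, "K_L": 105.0, "K_A": 668343.917568615, "n_stoich": 2.33},
    "adaptor_levels": [10.0, 39.81071705534972, 158.48931924611142, 630.957344480193, 2511.886431509581, 10000.0],
    "ligand_doses": [1.0, 3.727593720314938, 13.894954943731374, 51.7947467923121, 193.06977288832496, 719.6856730011514, 2682.6957952797255, 10000.0],
    "replicates": 3
  },
  "dose_response_hm3d": {
    "truth": {"bottom": 0.0, "top": 1.0, "EC50": 105.0, "hill_slope": 1.0},
    "doses": [1.0, 3.727593720314938, 13.894954943731374, 51.7947467923121, 193.06977288832496, 719.6856730011514, 2682.6957952797255, 10000.0],
    "replicates": 3
  },
  "dose_response_nmbr": {
    "truth": {"bottom": 0.0, "top": 1.0, "EC50": 13.0, "hill_slope": 1.0},
    "doses": [0.1, 0.3727593720314938, 1.3894954943731375, 5.17947467923121, 19.306977288832496, 71.96856730011514, 268.26957952797255, 1000.0],
    "replicates": 3
  },
  "dox": {
    "truth": {"kappa1": 100.0, "kappa2": 10.0, "K_D": 100.0, "n_hill": 1.0, "m": 1.0},
    "dox_levels": [1.0, 3.727593720314938, 13.894954943731374, 51.7947467923121, 193.06977288832496, 719.6856730011514, 2682.6957952797255, 10000.0],
    "replicates": 3
  },
  "pulse": {
    "rates": {
      "alpha_R": 1.0, "alpha_Rstar": 0.001, "alpha_A": 10.0,
      "beta_R": 0.1, "beta_Rstar": 0.1, "beta_A": 0.1,
      "beta_C": 0.02, "beta_G": 0.05, "gamma_C": 2.2e-06, "gamma_G": 0.01,
      "n_stoich": 2.33
    },
    "ligand_level": 10000.0,
    "pulse_start": 0.0,
    "pulse_end": 24.0,
    "followup_hours": 144.0
  }
}
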