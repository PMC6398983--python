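{
  "feedback_smad4": {
    "alpha": 65.65788147509086,
    "K_L": 20.0,
    "gamma": 16.07677815709552,
    "beta": 48.37914904951715,
    "delta": 0.7149447754422025,
    "K_I": 1.0,
    "S0": 1.0
  },
  "feedback_smad23": {
    "alpha": 65.65788147509086,
    "K_L": 20.0,
    "gamma": 16.07677815709552,
    "beta": 48.37914904951715,
    "delta": 0.7149447754422025,
    "K_I": 111.92447976178532,
    "S0": 1.0
  },
  "receptor": {
    "s": 1.0,
    "d_i": 0.2,
    "d_a": 1.0,
    "k_b": 10.0
  },
  "ligand_depletion": {
    "u": 0.15,
    "L_thresh": 1.0,
    "alpha": 2.0,
    "gamma": 2.0,
    "S0": 1.0,
    "n_hill": 4.0
  }
}
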