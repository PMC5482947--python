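{
  "_comment": "Default ICING glucose-insulin model constants (literature-sourced defaults, v1). Units: rates 1/min, volumes L, EGP/CNS mmol/min, alpha_G/alpha_I L/mU, u_en_* mU/min.",
  "_version": 1,
  "p_G": 0.006,
  "alpha_G": 0.0154,
  "alpha_I": 0.0017,
  "n_K": 0.0542,
  "n_L": 0.1578,
  "n_I": 0.006,
  "n_C": 0.006,
  "x_L": 0.67,
  "V_G": 13.3,
  "V_I": 4.0,
  "EGP": 1.16,
  "CNS": 0.3,
  "u_en_k1": 14.9,
  "u_en_k2": -49.9,
  "u_en_min": 16.7,
  "u_en_max": 266.7
}
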