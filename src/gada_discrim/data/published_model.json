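{
  "name": "published",
  "variables": [
    "age_lt30",
    "age_30to50",
    "bmi_lt23",
    "bmi_23to25",
    "tg_ge_cut",
    "hba1c_ge_cut",
    "hdl_ge_cut"
  ],
  "fisher": {
    "variables": [
      "age_lt30",
      "age_30to50",
      "bmi_lt23",
      "bmi_23to25",
      "tg_ge_cut",
      "hba1c_ge_cut",
      "hdl_ge_cut"
    ],
    "coefficients": {
      "GADA_POS": [5.556, 4.274, 6.030, 3.756, 2.525, 2.442, 4.658],
      "T2DM": [2.208, 2.576, 2.371, 2.421, 4.298, 0.911, 2.808]
    },
    "constants": {
      "GADA_POS": -7.917,
      "T2DM": -3.764
    }
  },
  "cutoffs": {
    "tg": 98.0,
    "hba1c": 8.6,
    "hdl": 46.0
  },
  "std_coefficients": [0.46, 0.36, 0.63, 0.22, -0.34, 0.32, 0.36],
  "loadings": [0.37, 0.11, 0.63, -0.11, -0.47, 0.30, 0.43],
  "eigenvalue": 1.106,
  "wilks_lambda": 0.475,
  "canonical_correlation": 0.725,
  "priors": null
}
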