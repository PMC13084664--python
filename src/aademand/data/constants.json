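{
  "io_rate": 0.29,
  "pto_pa_fraction": 0.11,
  "pto_pp_fraction": 0.024,
  "n_to_protein": 6.25,
  "body_weight": 75.0,
  "creatinine_excretion": 0.2,
  "nitrogen_loss": {
    "total_n": 5.0,
    "miscellaneous_n": 1.8,
    "total_n_sd": 0.9
  },
  "protein_requirement": {
    "mmd": 0.634,
    "fao": 0.66
  }
}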