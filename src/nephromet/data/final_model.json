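{
  "version": "1.0",
  "comment": "Published four-metabolite rejection-score model. The training-cohort standardization constants behind the I_x features were never published; a model file produced by a training run carries its own constants here.",
  "intercept": -3.0048615,
  "coefficients": {
    "alanine": -0.2527461,
    "citrate": -0.8224731,
    "lactate": 0.9502339,
    "urea": 0.2529190
  },
  "feature_order": ["alanine", "citrate", "lactate", "urea"],
  "standardization": null
}
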