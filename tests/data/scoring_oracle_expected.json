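{
 "dropped": [
  "AAA"
 ],
 "expected": {
  "KRA": {
   "mean_pos_freq": 0.16666666666666666,
   "mean_neg_freq": 0.05316666666666667,
   "mean_input_freq": 0.002375,
   "enrichment": 70.17543859649123,
   "neg_enrichment": 22.385964912280702,
   "selectivity": 3.134796238244514,
   "dispersion": 0.17320508075688776,
   "ln_score": 4.279099802378353,
   "n_placeholder_neg": 1,
   "n_placeholder_input": 2
  },
  "WHM": {
   "mean_pos_freq": 0.3,
   "mean_neg_freq": 0.034916666666666665,
   "mean_input_freq": 0.225,
   "enrichment": 1.3333333333333333,
   "neg_enrichment": 0.15518518518518518,
   "selectivity": 8.591885441527447,
   "dispersion": 0.33333333333333337,
   "ln_score": 1.203972804325936,
   "n_placeholder_neg": 1,
   "n_placeholder_input": 0
  },
  "YLN": {
   "mean_pos_freq": 0.5,
   "mean_neg_freq": 0.15,
   "mean_input_freq": 0.275,
   "enrichment": 1.8181818181818181,
   "neg_enrichment": 0.5454545454545454,
   "selectivity": 3.3333333333333335,
   "dispersion": 0.2,
   "ln_score": 1.3397743454849977,
   "n_placeholder_neg": 0,
   "n_placeholder_input": 0
  }
 }
}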