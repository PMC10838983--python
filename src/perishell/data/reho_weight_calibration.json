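{
 "noise_sd": 1.0,
 "lf_amplitude": 1.0,
 "tr_s": 2.0,
 "n_timepoints": 90,
 "weight_to_mean_reho": {
  "0.0": 0.0981,
  "0.1": 0.1002,
  "0.2": 0.1066,
  "0.3": 0.1172,
  "0.4": 0.1321,
  "0.5": 0.1515,
  "0.6": 0.1754,
  "0.7": 0.2041,
  "0.8": 0.2376,
  "0.9": 0.276
 }
}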