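{
  "library_condition_observed": 16.804430846601154,
  "library_condition_bound": 18,
  "noiseless_bias_oracle_max_err": 0.020926720365377793,
  "noiseless_bias_bound": 0.021346254772685352,
  "noisy_rmse_oracle_per_component": [
    0.033529348913164815,
    0.048400629609502845,
    0.0487525693871321,
    0.03200033414750287,
    0.022240156069314124
  ],
  "noisy_rmse_oracle_mean": 0.03698460762532335,
  "noisy_rmse_threshold": 0.03883383800658952,
  "k5_ssim_observed": [
    0.7927277129462794,
    0.7920212788254365,
    0.7988054348060509,
    0.7968748652691184,
    0.7964931681172989,
    0.7947794136053628,
    0.7951123283842454,
    0.791242848503604,
    0.788755163811579,
    0.798102868628005
  ],
  "k5_ssim_min": 0.788755163811579,
  "k5_ssim_threshold": 0.76,
  "ladder_monotone_all_seeds": true
}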