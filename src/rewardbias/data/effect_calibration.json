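{
 "description": "Scored participant mean criterion vs agent reward-learning rate, default schedule and agent, sensitivity drawn as in build_cohort",
 "n_sessions_per_point": 400,
 "seed": 20140,
 "sensitivity_mean": 1.7,
 "sensitivity_sd": 0.3,
 "grid": [
  {
   "learning_rate": -0.004,
   "mean_criterion": -0.2015392007127251,
   "sd_criterion": 0.09158181047808395
  },
  {
   "learning_rate": -0.002,
   "mean_criterion": -0.09327732654456682,
   "sd_criterion": 0.08726102944630391
  },
  {
   "learning_rate": 0.0,
   "mean_criterion": -9.479064468390128e-05,
   "sd_criterion": 0.08275556188664038
  },
  {
   "learning_rate": 0.002,
   "mean_criterion": 0.10620288888742525,
   "sd_criterion": 0.08247161896023537
  },
  {
   "learning_rate": 0.004,
   "mean_criterion": 0.1963632839233633,
   "sd_criterion": 0.09387444195656736
  },
  {
   "learning_rate": 0.006,
   "mean_criterion": 0.2982481023791608,
   "sd_criterion": 0.10845336121887955
  },
  {
   "learning_rate": 0.008,
   "mean_criterion": 0.40926703604064046,
   "sd_criterion": 0.11982953545875032
  },
  {
   "learning_rate": 0.01,
   "mean_criterion": 0.502038202114053,
   "sd_criterion": 0.12810477954397825
  }
 ]
}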