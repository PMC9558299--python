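{
  "label": "sensitive",
  "n_NS": 0.13,
  "j_ST0": 0.03,
  "sigma_NS": 0.9,
  "sigma_CS": 0.9,
  "y_CL": 0.1,
  "a_star": 1.34,
  "k_NPQ": 112,
  "k_ROS": 80,
  "j_CPm": 2.8,
  "j_SGm": 0.25,
  "b": 5
}
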