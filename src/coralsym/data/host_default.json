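{
  "n_NH": 0.18,
  "n_NX": 0.2,
  "j_HT0": 0.03,
  "sigma_NH": 0.9,
  "sigma_CH": 0.1,
  "j_Xm": 0.13,
  "K_X": 1e-06,
  "j_Nm": 0.035,
  "K_N": 1.5e-06,
  "k_CO2": 10,
  "j_HGm": 1,
  "y_C": 0.8
}
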