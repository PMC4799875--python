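{
  "alpha": 1.833,
  "beta": 0.1018,
  "gamma": 0.000399,
  "rho": 50.723
}
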