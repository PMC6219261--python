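{
  "a": -1.933,
  "b": 1.996,
  "x": 0.001876,
  "si_valid_max": 1200.0,
  "conc_valid_max": 15.0
}
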