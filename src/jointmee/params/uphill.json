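{
  "w0am": 9.31,
  "w1am": -1.64e-2,
  "w2am": -1.06e-1,
  "w3am": -2.10,
  "w4am": 7.68e-4,
  "w0sl": -9.03,
  "w1sl": 3.95e-2,
  "w2sl": 2.00e-1,
  "w3sl": 2.11,
  "w4sl": -2.24e-3
}
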