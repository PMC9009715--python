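{
  "w0am": -8.94e-1,
  "w1am": -4.87e-3,
  "w2am": -8.82e-3,
  "w3am": 8.77e-1,
  "w4am": 3.02e-2,
  "w0sl": 1.97,
  "w1sl": 4.37e-4,
  "w2sl": 4.67e-2,
  "w3sl": -9.76e-1,
  "w4sl": -1.17e-3
}
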