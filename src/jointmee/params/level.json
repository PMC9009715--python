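{
  "w0am": 4.49,
  "w1am": 1.35e-2,
  "w2am": -4.87e-2,
  "w3am": -1.39,
  "w4am": -6.64e-4,
  "w0sl": -1.46,
  "w1sl": -1.44e-2,
  "w2sl": 3.55e-3,
  "w3sl": 1.75,
  "w4sl": 2.32e-3
}
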