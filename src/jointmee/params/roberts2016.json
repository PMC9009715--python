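{
  "w0am": -2.27e-4,
  "w1am": -6.40e-7,
  "w2am": 1.61e-6,
  "w3am": 1.43e-4,
  "w4am": 1.82e1,
  "w0sl": 9.79e-1,
  "w1sl": 3.45e-4,
  "w2sl": 1.07e-2,
  "w3sl": -1.46e-1,
  "w4sl": -6.97e-5
}
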