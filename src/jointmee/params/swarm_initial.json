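{
  "level": {
    "w0am": -1.30e3,
    "w1am": 1.05e2,
    "w2am": -2.76e2,
    "w3am": 4.16e2,
    "w4am": -7.39e-3,
    "w0sl": 8.70e2,
    "w1sl": -1.24e2,
    "w2sl": 3.16e2,
    "w3sl": 5.51e1,
    "w4sl": -7.01e-3
  },
  "uphill": {
    "w0am": -3.27e3,
    "w1am": 1.28e2,
    "w2am": -1.12e2,
    "w3am": -1.34e3,
    "w4am": -5.52e-3,
    "w0sl": 4.69e2,
    "w1sl": -1.84e0,
    "w2sl": -2.33e2,
    "w3sl": 2.71e3,
    "w4sl": -5.91e-3
  },
  "downhill": {
    "w0am": -2.64e3,
    "w1am": 7.05e1,
    "w2am": -1.13e2,
    "w3am": 3.76e2,
    "w4am": -5.55e-3,
    "w0sl": 1.06e3,
    "w1sl": 8.52e1,
    "w2sl": -2.93e2,
    "w3sl": -4.10e1,
    "w4sl": -7.44e-3
  }
}
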