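{
  "IF": {
    "mean": -0.07619658,
    "sd": 0.38575543,
    "ts_se": 0.00623345
  },
  "ddir": {
    "mean": 0.28212734,
    "sd": 0.22035026,
    "ts_se": 0.00324049
  },
  "dind": {
    "mean": 0.35832392,
    "sd": 0.31668184,
    "ts_se": 0.00533981
  },
  "tau": {
    "mean": 0.19417591,
    "sd": 0.13214862,
    "ts_se": 0.00413558
  }
}
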