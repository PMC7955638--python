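{
  "weights": [1, 1, 1, 1, 0.8, 0.8, 0, 0, 1.2, 1.2, 1, 2],
  "note": "packaged default consensus weights for the 12 matching algorithms"
}
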