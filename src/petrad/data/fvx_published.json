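{
  "terms": [
    {"feature": "GLSZM_SzVarianc", "gray_level": 64, "weight": 0.128},
    {"feature": "NGTDM_Complex", "gray_level": 64, "weight": -0.018}
  ],
  "provenance": "published_fvx"
}
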