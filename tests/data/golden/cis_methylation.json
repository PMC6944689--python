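{
  "U": 0.0,
  "fraction_methylated_a": 0.33611111111111114,
  "fraction_methylated_b": 0.9434523809523809,
  "group_a": "BL",
  "group_b": "other",
  "p_value": 1.788055443745401e-12,
  "threshold": 0.3
}
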