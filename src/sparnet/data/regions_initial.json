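{
  "variant": "initial",
  "regions": {
    "C": ["E36", "E104", "E30", "E105", "E41", "E103", "E37", "E87", "E42", "E93", "E47", "E98"],
    "F": ["E19", "E4", "E22", "E9", "E24", "E124", "E27", "E123", "E32", "E1", "E33", "E128"],
    "O": ["E70", "E83", "E71", "E76", "E69", "E89", "E74", "E82", "E73", "E84", "E75", "E81"],
    "P": ["E52", "E92", "E60", "E85", "E51", "E97", "E67", "E77", "E59", "E91", "E72", "E62"],
    "T": ["E58", "E96", "E45", "E108", "E114", "E44", "E100", "E46", "E102", "E57", "E50", "E101"]
  },
  "substitutions": [
    {"region": "O", "original": "E83", "replacement": "E84", "substituted": true,
     "reason": "published channel-pair list repeats E83; nearest unused montage neighbour used"}
  ]
}
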