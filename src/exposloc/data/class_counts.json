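{
  "description": "Reference corpus size per location class (structure-resolved, curated training corpus)",
  "counts": {
    "N": 336,
    "Y": 347,
    "C": 543,
    "E": 132
  }
}
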