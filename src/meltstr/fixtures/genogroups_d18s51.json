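{
  "locus": "D18S51",
  "schemes": {
    "A": {"Group 1": ["(12,14)", "(12,15)"], "Group 2": ["(12,16)", "(13,16)"], "Group 3": ["(13,14)", "(14,15)"]},
    "C": {"Group 1": ["(12,14)", "(12,15)"], "Group 2": ["(12,16)", "(13,14)"], "Group 3": ["(13,16)", "(14,15)"]},
    "E": {"Group 1": ["(12,14)", "(12,15)", "(13,14)"], "Group 2": ["(12,16)"], "Group 3": ["(13,16)", "(14,15)"]},
    "F": {"Group 1": ["(12,14)", "(13,14)"], "Group 2": ["(12,15)", "(12,16)"], "Group 3": ["(13,16)", "(14,15)"]},
    "G": {"Group 1": ["(12,14)", "(12,15)"], "Group 2": ["(12,16)"], "Group 3": ["(13,14)", "(13,16)", "(14,15)"]}
  }
}
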