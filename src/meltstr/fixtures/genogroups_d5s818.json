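{
  "locus": "D5S818",
  "schemes": {
    "A": {"Group 1": ["(10,11)", "(11,13)"], "Group 2": ["(11,12)", "(12,12)"], "Group 3": ["(11,11)", "(12,13)", "(13,13)"]},
    "B": {"Group 1": ["(11,11)"], "Group 2": ["(11,12)", "(12,12)", "(12,13)"], "Group 3": ["(10,11)", "(11,13)"], "Group 4": ["(13,13)"]},
    "C": {"Group 1": ["(11,11)", "(13,13)"], "Group 2": ["(11,12)", "(12,12)", "(12,13)"], "Group 3": ["(10,11)", "(11,13)"]},
    "F": {"Group 1": ["(10,11)", "(11,13)"], "Group 2": ["(11,11)", "(12,12)"], "Group 3": ["(11,12)", "(12,13)", "(13,13)"]},
    "H": {"Group 1": ["(10,11)", "(11,11)"], "Group 2": ["(11,12)", "(12,12)"], "Group 3": ["(11,13)", "(12,13)", "(13,13)"]},
    "J": {"Group 1": ["(10,11)", "(11,12)"], "Group 2": ["(11,11)", "(12,12)"], "Group 3": ["(11,13)", "(12,13)", "(13,13)"]}
  }
}
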