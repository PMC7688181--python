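{
  "description": "Hand-specified synthetic 4x4 fixture lattice (torus). Types: 0=consensus, 1=reputation; attitudes: 0=a, 1=b; behaviors: 0=silent, 1=express. The cases list hand-derived local-state labels and next-step behaviors for selected cells.",
  "type_grid": [[0, 0, 1, 0], [0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1]],
  "attitude_grid": [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 1, 0], [1, 0, 0, 0]],
  "behavior_grid": [[1, 0, 0, 1], [0, 1, 0, 0], [0, 0, 1, 0], [1, 0, 0, 0]],
  "cases": [
    {"cell": [1, 2], "n_a": 1, "n_b": 1, "label": "stalemate", "next_behavior": 0,
     "why": "consensus seeker facing a 1-1 stalemate stays silent"},
    {"cell": [0, 2], "n_a": 1, "n_b": 0, "label": "partial_majority", "next_behavior": 0,
     "why": "reputation seeker never echoes the sole voiced opinion"},
    {"cell": [1, 0], "n_a": 2, "n_b": 0, "label": "partial_majority", "next_behavior": 0,
     "why": "consensus seeker with the minority attitude stays silent"},
    {"cell": [3, 3], "n_a": 1, "n_b": 1, "label": "stalemate", "next_behavior": 1,
     "why": "reputation seeker speaks into a stalemate"},
    {"cell": [1, 3], "n_a": 1, "n_b": 0, "label": "partial_majority", "next_behavior": 1,
     "why": "consensus seeker affirms the unopposed voiced opinion matching its attitude"},
    {"cell": [1, 1], "n_a": 0, "n_b": 0, "label": "total_silence", "next_behavior": 1,
     "why": "reputation seeker speaks into total silence"},
    {"cell": [2, 2], "n_a": 0, "n_b": 0, "label": "total_silence", "next_behavior": 0,
     "why": "consensus seeker stays silent under total silence"}
  ]
}
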