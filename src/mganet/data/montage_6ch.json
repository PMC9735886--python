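{
  "channels": [
    {"name": "F3", "xyz": [-0.5449, 0.673, 0.5]},
    {"name": "F4", "xyz": [0.5449, 0.673, 0.5]},
    {"name": "C3", "xyz": [-0.7071, 0.0, 0.7071]},
    {"name": "C4", "xyz": [0.7071, 0.0, 0.7071]},
    {"name": "O1", "xyz": [-0.309, -0.9511, 0.0]},
    {"name": "O2", "xyz": [0.309, -0.9511, 0.0]}
  ]
}
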