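{
 "model": "XYZInterrupted",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "cos_1_2", "type": "cos"},
  {"label": "sin_1_3", "type": "sin"},
  {"label": "tanh_1_4", "type": "tanh"},
  {"label": "floor_1_5", "type": "floor"},
  {"label": "cos_2_6", "type": "cos"},
  {"label": "sin_2_7", "type": "sin"},
  {"label": "tanh_2_8", "type": "tanh"},
  {"label": "ceil_1_9", "type": "ceil"},
  {"label": "cos_3_10", "type": "cos"},
  {"label": "sin_3_11", "type": "sin"},
  {"label": "tanh_3_12", "type": "tanh"},
  {"label": "output_1_13", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "cos_1_2", "arg0"],
  ["cos_1_2", "sin_1_3", "arg0"],
  ["sin_1_3", "tanh_1_4", "arg0"],
  ["tanh_1_4", "floor_1_5", "arg0"],
  ["floor_1_5", "cos_2_6", "arg0"],
  ["cos_2_6", "sin_2_7", "arg0"],
  ["sin_2_7", "tanh_2_8", "arg0"],
  ["tanh_2_8", "ceil_1_9", "arg0"],
  ["ceil_1_9", "cos_3_10", "arg0"],
  ["cos_3_10", "sin_3_11", "arg0"],
  ["sin_3_11", "tanh_3_12", "arg0"],
  ["tanh_3_12", "output_1_13", "arg0"]
 ],
 "layers": [
  {"label": "cos_1_2", "passes": 1},
  {"label": "cos_2_6", "passes": 1},
  {"label": "cos_3_10", "passes": 1}
 ]
}
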