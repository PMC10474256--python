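{
 "model": "XYZLoop",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "cos_1_2:1", "type": "cos"},
  {"label": "sin_1_3:1", "type": "sin"},
  {"label": "tanh_1_4:1", "type": "tanh"},
  {"label": "cos_1_2:2", "type": "cos"},
  {"label": "sin_1_3:2", "type": "sin"},
  {"label": "tanh_1_4:2", "type": "tanh"},
  {"label": "cos_1_2:3", "type": "cos"},
  {"label": "sin_1_3:3", "type": "sin"},
  {"label": "tanh_1_4:3", "type": "tanh"},
  {"label": "output_1_5", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "cos_1_2:1", "arg0"],
  ["cos_1_2:1", "sin_1_3:1", "arg0"],
  ["sin_1_3:1", "tanh_1_4:1", "arg0"],
  ["tanh_1_4:1", "cos_1_2:2", "arg0"],
  ["cos_1_2:2", "sin_1_3:2", "arg0"],
  ["sin_1_3:2", "tanh_1_4:2", "arg0"],
  ["tanh_1_4:2", "cos_1_2:3", "arg0"],
  ["cos_1_2:3", "sin_1_3:3", "arg0"],
  ["sin_1_3:3", "tanh_1_4:3", "arg0"],
  ["tanh_1_4:3", "output_1_5", "arg0"]
 ],
 "layers": [
  {"label": "cos_1_2", "passes": 3},
  {"label": "sin_1_3", "passes": 3},
  {"label": "tanh_1_4", "passes": 3}
 ]
}
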