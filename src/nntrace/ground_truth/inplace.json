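{
 "model": "InPlaceOp",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "cos_1_2", "type": "cos"},
  {"label": "add_1_3", "type": "add", "in_place": true},
  {"label": "sin_1_4", "type": "sin"},
  {"label": "output_1_5", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "cos_1_2", "arg0"],
  ["cos_1_2", "add_1_3", "arg0"],
  ["add_1_3", "sin_1_4", "arg0"],
  ["sin_1_4", "output_1_5", "arg0"]
 ],
 "layers": [{"label": "add_1_3", "passes": 1}]
}
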