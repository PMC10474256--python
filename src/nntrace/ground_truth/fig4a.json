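{
 "model": "Fig4A",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "cos_1_2:1", "type": "cos"},
  {"label": "linear_1_3:1", "type": "linear", "modules": ["fc:1"], "params": true},
  {"label": "add_1_4:1", "type": "add"},
  {"label": "sin_1_5", "type": "sin"},
  {"label": "cos_1_2:2", "type": "cos"},
  {"label": "linear_1_3:2", "type": "linear", "modules": ["fc:2"], "params": true},
  {"label": "add_1_4:2", "type": "add"},
  {"label": "output_1_6", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "cos_1_2:1", "arg0"],
  ["cos_1_2:1", "linear_1_3:1", "arg0"],
  ["linear_1_3:1", "add_1_4:1", "arg0"],
  ["add_1_4:1", "sin_1_5", "arg0"],
  ["sin_1_5", "cos_1_2:2", "arg0"],
  ["cos_1_2:2", "linear_1_3:2", "arg0"],
  ["linear_1_3:2", "add_1_4:2", "arg0"],
  ["add_1_4:2", "output_1_6", "arg0"]
 ],
 "layers": [
  {"label": "cos_1_2", "passes": 2},
  {"label": "linear_1_3", "passes": 2},
  {"label": "add_1_4", "passes": 2},
  {"label": "sin_1_5", "passes": 1}
 ]
}
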