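{
 "model": "BranchDivide",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "cos_1_2", "type": "cos"},
  {"label": "exp_1_3", "type": "exp"},
  {"label": "divide_1_4", "type": "divide"},
  {"label": "output_1_5", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "cos_1_2", "arg0"],
  ["input_1_1", "exp_1_3", "arg0"],
  ["cos_1_2", "divide_1_4", "arg0"],
  ["exp_1_3", "divide_1_4", "arg1"],
  ["divide_1_4", "output_1_5", "arg0"]
 ],
 "layers": [{"label": "divide_1_4", "passes": 1}]
}
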