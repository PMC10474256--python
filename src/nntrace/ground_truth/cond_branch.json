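{
 "model": "CondBranch",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "subtract_1_2", "type": "subtract", "flags": ["is_branch_start"]},
  {"label": "mean_1_3", "type": "mean"},
  {"label": "greater_1_4", "type": "greater", "flags": ["is_bool_terminal"]},
  {"label": "cos_1_5", "type": "cos"},
  {"label": "output_1_6", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "subtract_1_2", "arg0"],
  ["subtract_1_2", "mean_1_3", "arg0"],
  ["mean_1_3", "greater_1_4", "arg0"],
  ["subtract_1_2", "cos_1_5", "arg0"],
  ["cos_1_5", "output_1_6", "arg0"]
 ],
 "layers": [{"label": "greater_1_4", "passes": 1}]
}
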