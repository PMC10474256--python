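{
 "model": "OrphanOps",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "cos_1_2", "type": "cos"},
  {"label": "output_1_3", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "cos_1_2", "arg0"],
  ["cos_1_2", "output_1_3", "arg0"]
 ],
 "layers": [{"label": "cos_1_2", "passes": 1}]
}
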