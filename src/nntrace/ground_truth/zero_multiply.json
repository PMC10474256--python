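{
 "model": "ZeroMultiply",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "multiply_1_2", "type": "multiply"},
  {"label": "add_1_3", "type": "add"},
  {"label": "output_1_4", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "multiply_1_2", "arg0"],
  ["multiply_1_2", "add_1_3", "arg0"],
  ["add_1_3", "output_1_4", "arg0"]
 ],
 "layers": [{"label": "multiply_1_2", "passes": 1}]
}
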