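{
 "model": "WithBuffer",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "buffer_1_2", "type": "buffer", "flags": ["is_buffer"]},
  {"label": "subtract_1_3", "type": "subtract"},
  {"label": "output_1_4", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "subtract_1_3", "arg0"],
  ["buffer_1_2", "subtract_1_3", "arg1"],
  ["subtract_1_3", "output_1_4", "arg0"]
 ],
 "layers": [{"label": "buffer_1_2", "passes": 1}]
}
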