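{
 "model": "InternalRandom",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "rand_1_2", "type": "rand", "flags": ["is_internally_generated"]},
  {"label": "add_1_3", "type": "add"},
  {"label": "output_1_4", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "add_1_3", "arg0"],
  ["rand_1_2", "add_1_3", "arg1"],
  ["add_1_3", "output_1_4", "arg0"]
 ],
 "layers": [{"label": "rand_1_2", "passes": 1}]
}
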