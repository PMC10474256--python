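{
 "model": "TupleOutput",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "split_1_2", "type": "split"},
  {"label": "split_2_3", "type": "split"},
  {"label": "add_1_4", "type": "add"},
  {"label": "output_1_5", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "split_1_2", "arg0"],
  ["input_1_1", "split_2_3", "arg0"],
  ["split_1_2", "add_1_4", "arg0"],
  ["split_2_3", "add_1_4", "arg1"],
  ["add_1_4", "output_1_5", "arg0"]
 ],
 "layers": [{"label": "split_1_2", "passes": 1}, {"label": "split_2_3", "passes": 1}]
}
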