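{
 "model": "FeedForward",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "linear_1_2", "type": "linear", "modules": ["fc1"], "params": true},
  {"label": "relu_1_3", "type": "relu"},
  {"label": "linear_2_4", "type": "linear", "modules": ["fc2"], "params": true},
  {"label": "output_1_5", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "linear_1_2", "arg0"],
  ["linear_1_2", "relu_1_3", "arg0"],
  ["relu_1_3", "linear_2_4", "arg0"],
  ["linear_2_4", "output_1_5", "arg0"]
 ],
 "layers": [{"label": "linear_1_2", "passes": 1}, {"label": "linear_2_4", "passes": 1}]
}
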