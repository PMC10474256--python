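{
 "model": "Fig4B",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "cos_1_2:1", "type": "cos"},
  {"label": "relu_1_3:1", "type": "relu"},
  {"label": "multiply_1_4:1", "type": "multiply"},
  {"label": "cos_1_2:2", "type": "cos"},
  {"label": "relu_1_3:2", "type": "relu"},
  {"label": "multiply_1_4:2", "type": "multiply"},
  {"label": "tan_1_5", "type": "tan"},
  {"label": "cos_2_6", "type": "cos"},
  {"label": "relu_2_7", "type": "relu"},
  {"label": "multiply_2_8", "type": "multiply"},
  {"label": "output_1_9", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "cos_1_2:1", "arg0"],
  ["cos_1_2:1", "relu_1_3:1", "arg0"],
  ["relu_1_3:1", "multiply_1_4:1", "arg0"],
  ["multiply_1_4:1", "cos_1_2:2", "arg0"],
  ["cos_1_2:2", "relu_1_3:2", "arg0"],
  ["relu_1_3:2", "multiply_1_4:2", "arg0"],
  ["multiply_1_4:2", "tan_1_5", "arg0"],
  ["tan_1_5", "cos_2_6", "arg0"],
  ["cos_2_6", "relu_2_7", "arg0"],
  ["relu_2_7", "multiply_2_8", "arg0"],
  ["multiply_2_8", "output_1_9", "arg0"]
 ],
 "layers": [
  {"label": "cos_1_2", "passes": 2},
  {"label": "relu_1_3", "passes": 2},
  {"label": "multiply_1_4", "passes": 2},
  {"label": "cos_2_6", "passes": 1},
  {"label": "relu_2_7", "passes": 1},
  {"label": "multiply_2_8", "passes": 1}
 ]
}
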