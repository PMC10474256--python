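{
 "model": "NestedBlocks",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"]},
  {"label": "conv2d_1_2", "type": "conv2d", "modules": ["block1.branch1"], "params": true,
   "module_stack": ["block1", "block1.branch1"]},
  {"label": "conv2d_2_3", "type": "conv2d", "modules": ["block1.branch2.0"], "params": true,
   "module_stack": ["block1", "block1.branch2", "block1.branch2.0"]},
  {"label": "relu_1_4", "type": "relu", "modules": ["block1.branch2.1", "block1.branch2"]},
  {"label": "concatenate_1_5", "type": "concatenate", "modules": ["block1"],
   "module_stack": ["block1"]},
  {"label": "conv2d_3_6", "type": "conv2d", "modules": ["block2.branch1"], "params": true},
  {"label": "conv2d_4_7", "type": "conv2d", "modules": ["block2.branch2.0"], "params": true},
  {"label": "relu_2_8", "type": "relu", "modules": ["block2.branch2.1", "block2.branch2"]},
  {"label": "concatenate_2_9", "type": "concatenate", "modules": ["block2"]},
  {"label": "output_1_10", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "conv2d_1_2", "arg0"],
  ["input_1_1", "conv2d_2_3", "arg0"],
  ["conv2d_2_3", "relu_1_4", "arg0"],
  ["conv2d_1_2", "concatenate_1_5", "arg0[0]"],
  ["relu_1_4", "concatenate_1_5", "arg0[1]"],
  ["concatenate_1_5", "conv2d_3_6", "arg0"],
  ["concatenate_1_5", "conv2d_4_7", "arg0"],
  ["conv2d_4_7", "relu_2_8", "arg0"],
  ["conv2d_3_6", "concatenate_2_9", "arg0[0]"],
  ["relu_2_8", "concatenate_2_9", "arg0[1]"],
  ["concatenate_2_9", "output_1_10", "arg0"]
 ],
 "layers": [
  {"label": "conv2d_1_2", "passes": 1},
  {"label": "concatenate_1_5", "passes": 1},
  {"label": "concatenate_2_9", "passes": 1}
 ]
}
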