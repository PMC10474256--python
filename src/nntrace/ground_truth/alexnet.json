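{
 "model": "AlexNet",
 "entries": [
  {"label": "input_1_1", "type": "input", "flags": ["is_input"], "shape": [1, 3, 224, 224]},
  {"label": "conv2d_1_2", "type": "conv2d", "modules": ["features.0"], "params": true,
   "module_stack": ["features", "features.0"], "shape": [1, 64, 55, 55]},
  {"label": "relu_1_3", "type": "relu", "modules": ["features.1"]},
  {"label": "maxpool2d_1_4", "type": "maxpool2d", "modules": ["features.2"], "shape": [1, 64, 27, 27]},
  {"label": "conv2d_2_5", "type": "conv2d", "modules": ["features.3"], "params": true,
   "module_stack": ["features", "features.3"], "shape": [1, 192, 27, 27]},
  {"label": "relu_2_6", "type": "relu", "modules": ["features.4"]},
  {"label": "maxpool2d_2_7", "type": "maxpool2d", "modules": ["features.5"], "shape": [1, 192, 13, 13]},
  {"label": "conv2d_3_8", "type": "conv2d", "modules": ["features.6"], "params": true,
   "shape": [1, 384, 13, 13]},
  {"label": "relu_3_9", "type": "relu", "modules": ["features.7"]},
  {"label": "conv2d_4_10", "type": "conv2d", "modules": ["features.8"], "params": true,
   "shape": [1, 256, 13, 13]},
  {"label": "relu_4_11", "type": "relu", "modules": ["features.9"]},
  {"label": "conv2d_5_12", "type": "conv2d", "modules": ["features.10"], "params": true,
   "shape": [1, 256, 13, 13]},
  {"label": "relu_5_13", "type": "relu", "modules": ["features.11"]},
  {"label": "maxpool2d_3_14", "type": "maxpool2d", "modules": ["features.12", "features"],
   "shape": [1, 256, 6, 6]},
  {"label": "avgpool2d_1_15", "type": "avgpool2d", "modules": ["avgpool"], "shape": [1, 256, 6, 6]},
  {"label": "reshape_1_16", "type": "reshape", "shape": [1, 9216]},
  {"label": "dropout_1_17", "type": "dropout", "modules": ["classifier.0"]},
  {"label": "linear_1_18", "type": "linear", "modules": ["classifier.1"], "params": true,
   "shape": [1, 4096]},
  {"label": "relu_6_19", "type": "relu", "modules": ["classifier.2"]},
  {"label": "dropout_2_20", "type": "dropout", "modules": ["classifier.3"]},
  {"label": "linear_2_21", "type": "linear", "modules": ["classifier.4"], "params": true},
  {"label": "relu_7_22", "type": "relu", "modules": ["classifier.5"]},
  {"label": "linear_3_23", "type": "linear", "modules": ["classifier.6", "classifier"],
   "params": true, "shape": [1, 1000]},
  {"label": "output_1_24", "type": "output", "flags": ["is_output"]}
 ],
 "edges": [
  ["input_1_1", "conv2d_1_2", "arg0"],
  ["conv2d_1_2", "relu_1_3", "arg0"],
  ["relu_1_3", "maxpool2d_1_4", "arg0"],
  ["maxpool2d_1_4", "conv2d_2_5", "arg0"],
  ["conv2d_2_5", "relu_2_6", "arg0"],
  ["relu_2_6", "maxpool2d_2_7", "arg0"],
  ["maxpool2d_2_7", "conv2d_3_8", "arg0"],
  ["conv2d_3_8", "relu_3_9", "arg0"],
  ["relu_3_9", "conv2d_4_10", "arg0"],
  ["conv2d_4_10", "relu_4_11", "arg0"],
  ["relu_4_11", "conv2d_5_12", "arg0"],
  ["conv2d_5_12", "relu_5_13", "arg0"],
  ["relu_5_13", "maxpool2d_3_14", "arg0"],
  ["maxpool2d_3_14", "avgpool2d_1_15", "arg0"],
  ["avgpool2d_1_15", "reshape_1_16", "arg0"],
  ["reshape_1_16", "dropout_1_17", "arg0"],
  ["dropout_1_17", "linear_1_18", "arg0"],
  ["linear_1_18", "relu_6_19", "arg0"],
  ["relu_6_19", "dropout_2_20", "arg0"],
  ["dropout_2_20", "linear_2_21", "arg0"],
  ["linear_2_21", "relu_7_22", "arg0"],
  ["relu_7_22", "linear_3_23", "arg0"],
  ["linear_3_23", "output_1_24", "arg0"]
 ],
 "layers": [
  {"label": "conv2d_2_5", "passes": 1},
  {"label": "maxpool2d_3_14", "passes": 1},
  {"label": "linear_3_23", "passes": 1}
 ]
}
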