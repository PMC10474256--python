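# nntrace

Exhaustive forward-pass introspection for neural-network models built on
numpy: trace **every** tensor operation a model executes (not just module
outputs), assemble the full computational graph, name and index each layer,
verify the saved activations by re-execution, and render the graph as a
rolled or unrolled DOT diagram.

The package is aimed at computational neuroscientists and model engineers
who need hidden-layer activations and a faithful picture of a model's
structure — including models with branching, in-place ops, internally
generated tensors (noise injections), conditional if–then logic, and
recurrence via weight sharing — without editing model code.

## How it works

During one forward pass the tracer transiently wraps every public
tensor-returning routine of the host framework (the `numpy`,
`numpy.linalg` and `numpy.random` namespaces plus `nntrace.functional`,
which supplies layer-level ops such as `conv2d` and `dropout`). Each
outermost wrapped call logs one entry per output tensor — inputs and their
argument positions, non-tensor arguments, parameter identities, module
containment (tracked by forward hooks on `nntrace.nn` modules), timing,
and the RNG state before the call — and tags its outputs with a *barcode*
so later calls can recover their producers. Afterwards every routine is
restored to its original definition; the model's own output is unchanged.

Post-processing then: trims *orphan* operations that neither descend from
an input nor reach an output; computes shortest-path distances to the
input and output; flags childless single-element Boolean tensors as
if-test terminals and marks the inferred branch start; repairs the module
containment of internally generated tensors; and identifies recurrent
layers. A layer is *recurrent* when (1) the same trainable parameters are
applied more than once, (2) identical ops are adjacent to different passes
of such a layer (applied recursively), or (3) a parameter-free op sequence
repeats back-to-back (`XYZXYZXYZ` is a loop; `XYZAXYZBXYZ` is not).

Layers are named `{layer_type}_{layer_type_num}_{layer_total_num}` — e.g.
`relu_3_6` is the third ReLU and sixth layer overall — with `:{pass}` for
repeated layers, and are also addressable by the module whose output they
produce (e.g. `features.12`, at every nesting level for which that holds).

Validation re-executes each layer's routine on the saved values of its
parents (restoring the captured RNG state, so stochastic layers replay
exactly) and checks the result against the saved activation; as a
counter-check, random substitute parents must change the output unless the
op is input-insensitive (e.g. multiplication by zero).

## Worked example

A model applies the *same* linear layer twice — `cos → fc → add → sin →
cos → fc → add` — so the cosine, linear and addition ops each have two
passes:

```python
import nntrace

model, x, _ = nntrace.make_fixture("fig4a", seed=1)
history = nntrace.log_forward_pass(model, x, seed=1)
print(history)
print(" ".join(history.layer_labels()))
```

prints

```
ModelHistory for Fig4A:
  layers: 9
  tensor operations: 7 (112 B of computed tensors)
  trainable parameters: 20 (80 B)
  forward pass time: 0.72 ms
input_1_1 cos_1_2:1 linear_1_3:1 add_1_4:1 sin_1_5 cos_1_2:2 linear_1_3:2 add_1_4:2 output_1_6
```

Nine executed entries collapse to six layers; the shared fully-connected
layer is `linear_1_3` (third layer overall, two passes). In the rolled
graph the cosine layer's inputs differ across passes:

```python
cos = next(n for n in history.rolled_nodes if n.label == "cos_1_2")
for (src, pos), pairs in sorted(cos.incoming.items()):
    print(f"cos_1_2 <- {src} on passes {[d for _, d in sorted(pairs)]}")
# cos_1_2 <- input_1_1 on passes [1]
# cos_1_2 <- sin_1_5 on passes [2]

nntrace.validate_saved_activations(model, x, seed=1)   # True
```

Layers can be fetched by any alias — `history["linear_1_3"]`,
`history["linear_1"]`, `history["fc:2"]`, `history[-2]` — and queried
programmatically, e.g. all pooling layers with a ReLU parent:

```python
meta = nntrace.get_model_metadata(model, x)
nntrace.select_layers(meta, lambda e: e.layer_type == "maxpool2d"
                      and any(p.layer_type == "relu" for p in e.parent_layers))
```

A thin CLI mirrors the library:

```bash
nntrace graph fixture:fig4a --rolled --out g.dot     # DOT with "(×2)" nodes
nntrace validate fixture:fig4b --seed 1              # exit 0 iff valid
nntrace log fixture:alexnet --layers relu --out acts/
```

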