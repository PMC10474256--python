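# Methods

This note documents the model of a forward pass that `nntrace` implements,
the design decisions taken where several were defensible, and the limits
of what the test fixtures demonstrate.

## The tracing model

A model's forward pass is treated as a finite sequence of calls to
tensor-returning routines of the host framework. `nntrace` wraps, for the
duration of one `TraceSession`, every public callable of `numpy`,
`numpy.linalg`, `numpy.random` and `nntrace.functional` that is not on a
deny-list (serialization, printing, RNG state management, error-state
plumbing — routines whose wrapping would corrupt interpreter state or
recurse into the logger). The wrap list is discovered by namespace
introspection at session start rather than hard-coded, so it tracks the
framework version; wrapping a routine that never returns a tensor is
harmless because the wrapper only logs calls whose outputs contain
tensors (others are counted as skipped).

Key behaviors of the logging wrapper:

- **One node per user-visible call.** When a wrapped routine's
  implementation invokes other wrapped routines (e.g. `conv2d` calling
  `matmul`), only the outermost call is logged, via a re-entrancy depth
  counter. This also makes the recorded duration the wall-clock self-time
  of the user-visible call, with no double counting.
- **Barcodes.** Every output tensor is tagged (keyed by object identity,
  with the session holding a strong reference so identities cannot be
  recycled) with a fresh barcode pointing at its producing entry. numpy
  returns cached singleton objects for 0-d results (e.g. booleans), which
  would alias distinct operations; the wrapper therefore converts scalar
  outputs of logged calls to fresh 0-d arrays. Observational transparency
  is consequently asserted on values/shape/dtype rather than on Python
  object types.
- **In-place ops.** A call that writes into an `out=` destination yields
  a new entry whose parents are the call's *data* arguments (the
  destination is not a parent), and the mutated tensor is re-tagged with
  a fresh barcode, so prior and subsequent consumers attach to the right
  entries. For the common `f(x, out=x)` pattern this reduces to a single
  parent: the mutated tensor's previous entry.
- **Tuple-returning ops** produce one entry per output tensor, sharing
  call metadata and carrying an output index; sibling outputs of one call
  are never treated as repetitions of each other.
- **Origins.** Model inputs, buffers (non-trainable registered tensors)
  and unknown tensors first seen as arguments (constants created inside
  the model) become origin entries; creation ops with no tensor parents
  (e.g. `rand`) are flagged internally generated.
- **RNG capture.** The global generator state is snapshotted before every
  logged call. Tracing itself never draws from the generator, so a traced
  run consumes exactly the same random stream as an untraced run — this
  is what makes exact replay (and hence validation of stochastic layers)
  possible.
- **Module containment** is tracked by forward pre/post hooks on every
  named submodule: entering pushes the module address on a stack recorded
  by subsequent entries; leaving pops it and marks the entry that
  produced the module's returned tensor with that module's address (at
  every nesting level for which this holds). A module executed more than
  once gets pass-qualified addresses (`fc:2`).

Restoration is guaranteed by a `finally` block: after any session,
including one that raised inside the model, every wrapped attribute is
reset to its original object, and a sweep helper (`residual_wrapper_count`)
can verify this.

## Post-processing

Applied in order:

1. **Orphan trimming** removes exactly the entries that neither descend
   from any input nor reach any output. Dead ends that do descend from
   the input are kept — they are candidate conditional tests.
2. **Distances**: shortest directed path (edge count) from any input and
   to any output, `None` where unreachable (never infinity).
3. **Branch inference**: a childless single-element Boolean entry is a
   plausible if-test terminal; walking its ancestry backwards
   breadth-first, the nearest ancestor that also reaches the model output
   is marked as the branch start (earliest in execution order on ties).
4. **Containment repair**: entries not descended from the input (noise
   and constants, and their pre-join transforms) take the module stack of
   their nearest input-descended descendant, found by forward
   breadth-first search, so internally generated tensors are displayed
   inside the module that consumes them.
5. **Recurrence grouping** by three rules: shared-parameter ops always
   group; identical ops (same routine, parameter identity, canonicalized
   non-tensor arguments, output index) adjacent to *different* passes of
   an existing multi-pass group merge, recursively to fixpoint; and
   parameter-free blocks that repeat back-to-back in execution order
   group position-wise. Block search is greedy from the earliest start;
   ties prefer the largest covered span, then the shortest period (most
   passes). Execution-order contiguity is used as the adjacency criterion
   for rule 3; grouping ignores module containment (an op repeated inside
   a different module still merges if its signature matches).
6. **Rolling** collapses each group to one node and annotates every edge
   with the (source-pass, destination-pass) pairs it serves; an
   annotation is printed only when an edge is not active on all passes
   of the corresponding node ("In 1", "Out 2-3").

The unrolled graph is acyclic by construction (parents always precede
children in execution order); cycles can appear only in the rolled view
through multi-pass nodes.

## Naming and indexing

Default labels are `{type}_{type_num}_{total_num}` with `:{pass}` for
multi-pass layers. Global numbering is over layers (groups) in order of
first execution and includes input, output, buffer and constant origin
entries — so in the shared-linear example the input is layer 1 and the
shared linear layer is `linear_1_3`. Layer-type tokens are lowercased
canonical routine names with a small alias table (e.g. numpy's `concat`
alias maps to `concatenate`). `ModelHistory` resolves full labels,
truncated labels (`relu_3`), pass labels, module addresses at any nesting
level, and integer ordinals (negative allowed); when only a subset of
layers is saved, integer indexing runs over the saved layers only.
Unknown keys raise with near-miss suggestions.

## Validation

Each layer's stored routine is re-executed on copies of its parents'
saved activations, after restoring the RNG state captured at logging
time, and must reproduce the saved activation within `rtol=1e-5`,
`atol=1e-8` elementwise for float tensors (exact equality for integer and
Boolean tensors). Bitwise identity is not demanded because floating-point
re-execution is not guaranteed stable across op orderings; in practice
re-execution is deterministic here and deviations are zero. As a
counter-check, standard-normal substitutes scaled and shifted to the
saved parent's moments must change the output; the check is skipped for
structurally input-insensitive ops (multiplication by a zero literal,
empty tensors) or when two distinct substitutes produce identical outputs
(an empirical insensitivity fallback that also covers saturated
comparisons). The walk starts at the model outputs *and every childless
entry* and recurses to parentless origins: starting only at the outputs,
as a strict outputs-backwards recursion would, can never reach dead-end
conditional-test chains, leaving those layers unvalidated. Substitute
draws are seeded from (session seed, layer label), so validation is
reproducible.

## Visualization

The DOT serializer is part of the package (no graphviz bindings are
required; rendering to PNG/PDF is attempted only if a `dot` executable is
on PATH, otherwise source is emitted with a warning). The style table
fixes concrete values for the visual code — pale green `#98fb98` inputs,
light red `#ff9999` outputs, gray `#c8c8c8` parameterized layers, light
gray `#f2f2f2` buffers, yellow `#ffff99` Boolean terminals, dashed
outlines for internally generated tensors, a bold `IF` on the branch
start, ellipses for free ops and rectangles for bottom-level module ops —
the named colors are fixed choices; the exact shades are a matter of
style. Argument positions are labeled only for non-commutative ops with
several tensor parents, and keyword arguments by name. `nesting_depth`
collapses modules deeper than the given level into single nodes; node
count is non-decreasing in depth.

## Synthetic fixtures and what the tests show

All tests run on programmatically built models with seeded random weights
and inputs: toy recurrence/branching/noise/buffer/in-place/tuple models,
two parameter-free loop patterns, a two-block inception-style model, and
a standard AlexNet stack (conventional 224×224 input, 61M parameters,
randomly initialized — only the architecture matters, so no pretrained
checkpoints are downloaded). Fixture inputs are otherwise small
(≤ 1×4×8×8). Each fixture carries a hand-written ground-truth graph
(labels, flags, adjacency with argument positions, pass counts, module
addresses) against which the traced history is compared node-for-node and
edge-for-edge. Graph algorithms are cross-checked against networkx as an
independent oracle.

These fixtures exercise the mechanisms, not the scale, of real model
zoos: passing tests show the tracer is observationally transparent,
complete and restorable on the covered op vocabulary, not that every
routine of the framework has been exercised. The conditional-branch
fixture draws inputs from [0, 1) so the traced branch is stable across
seeds; as with any dynamic-control-flow model, the logged graph describes
the branch actually taken for the given input.

## Known limitations

- Operator syntax on plain arrays (`x + y`) dispatches at the C level and
  bypasses the wrapped namespaces; model code (and the bundled `nn`
  layers) should use the functional forms (`np.add`, `F.relu`, …) for
  those ops to be logged.
- Routines that mutate an argument and return nothing (`np.copyto`) are
  not modeled as graph nodes.
- Backward passes, gradients and multi-process execution are out of
  scope; tracing is single-threaded.
- Validation requires all intermediate activations to be saved, which is
  memory-hungry for large models (the AlexNet fixture's saved pass is a
  few tens of MB).
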