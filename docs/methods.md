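# Methods

## The federated procedure

The simulator models the cross-silo setting — a handful of reliable
institutional clients, all participating every round — in one process.
One run consists of:

1. **Pooling and splitting.** All labelled images are pooled, shuffled
   under a fixed seed, and split 90:10 into a training pool and a single
   central test set shared by every client count (no per-client test
   sets). The split is delegated to scikit-learn's `train_test_split`.
2. **Sharding.** The training pool is shuffled under the run seed and cut
   into `n_clients` contiguous, near-equal shards ("clients_1", …). Sizes
   differ by at most one; the first `N mod n_clients` shards take the
   extra sample. Shards are IID by construction; label-skewed partitions
   are out of scope.
3. **Local update.** Each client copies the current global parameters and
   runs `epochs` passes of mini-batch SGD with momentum over a per-epoch
   seeded reshuffle of its shard (final partial batch included). After
   every epoch the loss over the whole shard is recorded; the snapshot of
   the best (lowest-loss, earliest on ties) epoch is returned. The
   initial parameters are not a candidate, so with a single full-batch
   epoch the result is exactly one optimizer step — a property the tests
   exploit. The global model is never mutated.
4. **Aggregation.** Each returned model is scaled by its client's weight
   scaling factor `n_k / n` and the scaled tensors are summed in fixed
   client order (FedAVG). Since the factors sum to 1 this is the
   data-weighted average; for the equal shards actually produced it
   reduces to the unweighted mean.
5. **Evaluation and selection.** The aggregate is scored on the central
   test set (accuracy by argmax with ties broken toward the first class;
   mean cross-entropy loss). After the last round the round minimizing
   the global loss — earliest on ties — supplies the optimal model `w*`.
   Wall-clock time per round is recorded but is informational only:
   it is hardware-dependent and never asserted.

"In parallel" is simulated sequentially; the contract is that the
aggregate is independent of client order (exercised to 1e-10 across
orders), not actual concurrency.

## The base model and optimizer

A 3-layer MLP: input `h*w*channels` (row-major flattening, fixed), two
dense ReLU layers of 200 units, and a softmax output over 2 classes. Loss
is mean categorical cross-entropy with the predicted probability floored
at 1e-12 inside the logarithm. Backpropagation is analytic and is held to
central finite differences (step 1e-5, relative error ≤ 1e-4) over
repeated random nets.

The optimizer is classical (non-Nesterov) momentum SGD,
`v ← βv − λ_t g`, `w ← w + v`. The `decay` parameter is interpreted as
learning-rate decay `λ_t = λ/(1 + decay·t)` with `t` the per-client step
count — the conventional meaning for an SGD optimizer's decay knob; an
`l2` weight-decay mode is available as a config alternative
(`decay_mode="l2"`). Velocity resets at the start of every local update;
momentum state is not federated.

**Initialization.** Hidden weights are Glorot-uniform under the run seed;
all biases and the output-layer weights start at zero. The zero output
layer makes the untrained network emit exactly uniform probabilities, so
the starting global loss is analytically ln 2 ≈ 0.6931 on any two-class
set and the starting accuracy on a balanced set is 0.5 (argmax tie-break
to the first class). This gives the pipeline an exact, testable anchor —
and matches the familiar observation that two-class cross-entropy training
plateaus near 0.69 when a model has learned nothing.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| `batch_size` | 32 | local mini-batch size |
| `learning_rate` | 1e-4 | base SGD rate λ |
| `momentum` | 0.9 | velocity coefficient β |
| `decay` | 1e-6 | learning-rate decay per step |
| `epochs` | 10 | local passes per round (E) |
| `rounds` | 100 | communication rounds (R) |
| `n_clients` | 2 | participating silos (2–5 typical) |
| `seed` | 42 | shuffle/split/init seed |
| `split_ratio` | 0.9 | train fraction of the pool |
| `image_size`, `channels` | 28×28, 1 | input geometry |
| `hidden_units` | 200 | width of both hidden layers |

The input geometry is configurable rather than fixed because published
descriptions of this kind of pipeline are frequently ambiguous about it
(e.g. a stated 28×28×3 resize alongside a 50,176-dimensional input layer,
which equals 224² and implies a single channel). The package defaults to
28×28×1 for desk-scale runs and leaves both knobs explicit; when
`channels=3` the grayscale channel is replicated.

A related ambiguity is the client-count template: tutorial-style
implementations often create a large fixed roster (e.g. 100 named
clients) and then train 2–5 of them over the whole pool. The simulator
creates exactly the participating shards.

## The synthetic data generator

`SynthSpec` defaults describe the standard study conditions used
throughout the tests: 600 images, 28×28 grayscale, balanced classes,
opacity intensity 120, noise SD 20, data seed 7. The opacity radius (5 px
on a 28 px frame) is the one free choice; it was set once as a plausible
consolidation size relative to the frame and is validated only through the
separability checks. Both classes share a fixed vignette (20 at the
borders to 100 at the centre on the 0–255 scale) so that the *only*
between-class signal is the patch — this is what licenses the
one-parameter mean-pixel threshold classifier as an independent oracle:
it reaches ≥ 0.9 held-out accuracy under the default conditions, and its
accuracy is non-decreasing in opacity intensity at fixed noise.

What the generator does **not** emulate: anatomy (no ribs, mediastinum or
lung boundaries), class-conditional background variation, scanner and
exposure heterogeneity, label noise, multi-focal or diffuse opacities,
and non-IID client distributions. Consequently, passing tests show the
*mechanics* are correct — sharding, optimization, aggregation, selection,
serialization — not that the model would attain any particular accuracy
on real radiographs. Published accuracies obtained on pooled public
chest-X-ray collections (tens of thousands of images, 100 rounds) are
stochastic outcomes of that external data and are deliberately not
reproduction targets here.

## Numerical and design choices

- **Determinism.** Identical datasets, configs and seeds give bitwise
  identical runs. Per-round, per-client RNG streams are derived with
  `SeedSequence([seed, round, client_index])`, so clients are
  decorrelated but reproducible; summation in the aggregate runs in fixed
  client order.
- **Desk-scale study conditions.** The convergence property (and the
  acceptance script) runs 2 clients on the 600-image synthetic set with
  λ = 0.01 and E = 5 for ≤ 30 rounds — the learning rate is raised above
  the full-scale default so the run completes in seconds while exercising
  every stage; criterion is ≥ 0.90 global accuracy within 30 rounds in at
  least 4 of 5 training seeds (1–5).
- **Ties.** Argmax prediction ties break to the lowest class index;
  argmin selection ties (rounds or epochs) break to the earliest.
- **Normalization guard.** `normalize_pixels` demands integer 0–255
  input and names the first offending index otherwise, so accidentally
  normalizing twice fails loudly; an all-{0,1} input (a plausible binary
  mask) is accepted with a warning.
- **Degenerate inputs.** Empty shards, empty test sets, empty histories,
  unknown client ids and unknown labels are rejected with messages naming
  the offender; undecodable image files are skipped and counted.
- **Memory hygiene.** Transient copies inside the round loop are held as
  raw tensor lists and released eagerly; at no point are more than
  `n_clients + 2` model-parameter objects alive (the clients' scaled
  models, the global model, and the running best). A weakref-based
  counter on `ModelParams` makes the bound a test rather than a comment.
- **Checkpoint format.** `w*` is saved as an NPZ archive of named float64
  tensors plus a JSON header (shapes and caller metadata); round-trips
  are bit-exact. Metrics CSVs are written with shortest-round-trip float
  formatting and read back with `float_precision="round_trip"`, so they
  survive serialization at full precision.

## Known limitations

Single-machine simulation only (no transport, stragglers, dropout or
privacy accounting); IID equal shards only; FedAVG only (no FedProx or
robust aggregation); a fixed 2-class vocabulary; no data augmentation;
CPU float64 NumPy execution, so very large images or client counts are
out of scope by design.
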