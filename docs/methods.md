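# Methods

## Network model

Each network has a single hidden layer of `N` nodes. Hidden-hidden
connectivity is a directed Erdős–Rényi draw: every ordered pair (i, j),
i ≠ j, is connected independently with probability `p`. Self-connections
are excluded, so the density `D = E/[N(N−1)]` is an unbiased estimate of
`p`; per-edge Bernoulli sampling (rather than a fixed edge count) is used
because the wiring is meant to model a connection *probability*. Input and
readout layers are always fully connected.

The forward computation is

    h_t = φ(x_t W_in + h_{t−1} (W_hh ⊙ M)),  t = 1…T,  h_0 = 0,
    logits = h_T W_out

with no biases (configurable nowhere on purpose: the readout sees only the
final hidden state, and adding biases would change the dropout and
activation-sparsity analyses, which assume a zero resting output). The
feedforward control splits the `N` hidden nodes 50/50 into two layers,
masks the inter-layer weights at `p`, and consumes the flattened sequence
in a single step.

ReLU is the default activation; it gives nodes a firing threshold (net
input below zero produces exactly zero output), which is what makes the
"fraction of nonzero activations" analyses meaningful. tanh is provided as
the symmetric, threshold-free control.

## Initialization

All weights are drawn uniformly from ±0.001 (`weight_init_bound`). Under
Dale's principle, node signs are assigned first — exactly
`round(f·N)` inhibitory nodes at uniformly random positions, so the default
cortical fraction f = 0.115 is honored deterministically rather than in
expectation — and outgoing weights of node i are `|U(0, 0.001)| · sign_i`,
for both the recurrent rows and the readout rows ("outgoing" is read as
covering every weight the node sends, including to the output layer). The
input projection has no E/I identity and stays unsigned. The
strengthened-inhibition manipulation multiplies inhibitory initial
magnitudes by `inhibitory_scale` (10 in the standard manipulation); the
balanced control sets f = 0.5.

## Training

Adam (lr 0.001, β₁ = 0.9, β₂ = 0.999) on mean cross-entropy, batch size 100
(batch size is a free choice; 100 keeps desk-scale epochs at tens of
steps). Training data are reshuffled every epoch from a seeded generator;
test accuracy is evaluated on the full test split after every epoch.

Two projections run after each optimizer step, in this order:

1. **Mask projection** — masked entries of `W_hh` are reset to exactly 0.
   The gradient is also masked before the step, so Adam's moment estimates
   never accumulate for non-existent edges. In `sparse_to_dense` mode both
   are skipped: the mask shapes only the initial weights and every entry is
   trainable.
2. **Dale projection** — any entry of `W_hh` or `W_out` whose sign is
   opposite its node's identity is set to exactly 0. The entry remains
   trainable: its gradient can later move it away from zero in the
   permitted direction. Optimizer moments are *not* reset on clipping
   (simplest projection; resetting them is a second-order concern at
   lr 0.001 and would couple the optimizer to the constraint).

Gradients are computed by hand-derived backpropagation through time
(float64 throughout). The ReLU derivative at exactly 0 is taken as 0. A
central-finite-difference oracle over every weight of a small network pins
the implementation to relative tolerance 1e−4.

Early stopping (used for data-limited experiments) halts when test accuracy
has not improved for `early_stop_patience` epochs (default 5 when enabled;
the criterion "performance stopped improving" leaves the patience open, and
5 is forgiving enough not to truncate slow learners at desk scale).
Training-delay experiments instead stop as soon as accuracy first exceeds
chance + margin, since the delay is then determined.

## Analyses

All representation analyses use the final-timestep activations — the only
vector the readout sees.

* **Nonzero fraction**: per test sample, the fraction of nodes with
  activation strictly > 0.
* **Pairwise mutual information**: node pairs sampled without replacement
  (default 10,000), MI per pair estimated with scikit-learn's k-NN
  regression estimator (k = 3, the estimator's default neighborhood),
  reported in **nats** (multiply by 1/ln 2 for bits). A pair with a
  constant node is defined as MI 0; small negative estimates are clipped to
  0 and counted.
* **Initialization correlations**: Pearson R between node activation
  vectors over a probe set; constant nodes are excluded and counted; pairs
  are subsampled (seeded) with the same scheme as the MI analysis when the
  full pair set is infeasible.
* **Dropout robustness**: for each test sample independently (and per
  repeat), a uniformly random subset of `round(f·N)` nodes has its final
  output zeroed before the readout; survivors are not rescaled. Fraction 0
  reproduces the undropped accuracy bit-exactly; fraction 1 forces all-zero
  logits, and the documented argmax tie rule (lowest class index) then
  predicts class 0 for every sample. Accuracy need not be monotone in the
  fraction and is never asserted to be.
* **Training delay**: the smallest 1-based epoch whose test accuracy
  strictly exceeds `1/n_classes + margin`, or "never". The margin defaults
  to 0.02 — the bare definition ("exceeds chance") has no tolerance, and
  0.02 sits several binomial standard errors above chance for the test-set
  sizes used here, so epoch-to-epoch noise does not trigger a crossing. A
  sustained-crossing variant (two consecutive epochs) is available.

## Synthetic task generator

The generator emulates the statistical contract of row-scanned images:
non-negative, bounded inputs with class-dependent spatiotemporal structure.
Each class gets one fixed `T×d` template with 30% nonzero entries
(mostly-dark, like digit images) whose values lie in [0.3, 1] — clearly
above the noise floor; samples are the template temporally shifted by a
uniform integer in ±1 (circularly), plus Gaussian noise (sd 0.1), clipped to
[0, 1]. Defaults: 10 classes, T = d = 28, 200 train / 100 test samples per
class — a desk-scale stand-in for the 6,000-per-class image benchmarks.
Train and test draws are independent streams from one seed; class balance
is exact.

What the generator does **not** emulate: within-class style variability
(every sample shares one template), pixel-intensity statistics of natural
images, and inter-class correlation structure. Passing tests on this task
show that the pipeline's mechanics and orderings are right, not that
absolute accuracies transfer to image benchmarks.

Uniform-noise probe sequences (`make_probe_inputs`) are used for analyses
of untrained networks, where only the network's intrinsic structure should
matter.

## Desk-scale experiment sizes

The package's own experiments run at 512–2048 hidden nodes: single-epoch
sparse/dense comparisons at N = 512, Dale delay comparisons at N = 1024,
initialization-correlation probes at N = 2000, three seeds per condition.
These sizes preserve the sparse/dense orderings while remaining single-CPU
friendly; the full-size grids (10,000–24,000 nodes, 10 seeds) are the same
code at larger settings and GPU-scale budgets.

One size-dependence worth stating explicitly: the E/I-imbalance mechanism
is driven by the mean recurrent gain, roughly `N·p·(b/2)·(f_E − f_I)` with
`b` the init bound. With b = 0.001 and the cortical E/I fraction this gain
crosses 1 only for `N·p` in the several-thousands, so dense Dale networks
at N ≈ 1024 sit below the runaway-excitation regime and may show no
absolute delay on an easy task. The delay experiments therefore assert the
robust *ordering* (dense delay ≥ sparse delay; balance abolishes the dense
delay), not delay magnitudes, which at full scale reach tens of epochs.

## Known limitations

* No biases, no temporal pooling, exactly `T` input presentations —
  deliberate modeling choices, not configurable surface.
* The MI estimator inherits the k-NN estimator's bias for heavily tied
  data; the test suite bounds it against an exact histogram oracle on
  discretized records (0.05 nats at n = 5,000).
* `matched_parameter_grid` breaks ties in the weight-budget match toward
  the larger network.
* Checkpoints and dataset caches are HDF5; experiment logs are
  line-delimited JSON and CSV.
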