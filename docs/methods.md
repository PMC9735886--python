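# Methods

## Problem setting

Sleep staging assigns one of five AASM classes (W, N1, N2, N3, REM; fixed
in this order everywhere in the package) to each 30-s epoch of a
multichannel EEG recording. Two structures carry most of the information:
the spatial arrangement of electrodes (channels interact unevenly, and the
interactions are not grid-like) and the temporal persistence of stages
(sleep moves through stages slowly, so neighbouring epochs are strongly
informative). The classifier combines a graph-attention treatment of the
first with a recurrent treatment of the second, and adds a stage-level
attention head aimed at transitional epochs, whose features blend adjacent
stages and dominate the error budget of human and automatic scorers alike.

## Electrode graph

The montage is a set of named electrodes with 3D unit-sphere coordinates.
Edges come from a k-nearest-neighbour rule (Euclidean distance,
`k = 3` by default, configurable), OR-symmetrized so the graph is
undirected; distance ties break toward the lower channel index so graph
construction is bit-reproducible across platforms. Self-loops are
excluded: a node's own features enter the attention computation explicitly
in the score's centre slot, not through the adjacency matrix. The packaged
default montage is F3, F4, C3, C4, O1, O2 at idealized 10–20 positions.
The channel set is fully user-configurable; nothing restricts nodes to EEG
derivations.

## Node features

Each channel of each epoch is summarized by log mean periodogram power in
the five standard sleep bands: delta 0.5–4, theta 4–8, alpha 8–13, sigma
11–16 (spindles; overlapping alpha deliberately), beta 16–30 Hz. The
periodogram uses a mean-removed segment and no taper by default (Hann
available); the feature is `log(1e-12 + mean band power)`. Scaling the
signal by c therefore shifts every feature by exactly `2 log c`, and
features of one channel never depend on another channel's samples.
Per-(channel, band) z-scoring across the recording's epochs is applied by
default before model input. The choice of featurization — band log power
with F = 5 — is this package's own; it fixes the node feature dimension
concretely and keeps the spectral fingerprints of the five stages
linearly well-separated.

## Model

**Masked multi-head graph attention.** One head on centre node c with
neighbourhood N(c): scores `u_ck = LeakyReLU(aᵀ[W f_c ‖ W f_k])` with
negative slope fixed at 0.2, softmax-normalized over N(c) only —
non-neighbours get exactly zero weight, enforced by masking rather than by
additive −∞ tricks, so the zero is exact. The layer output is the
logistic of the head-averaged weighted neighbour sum (head *averaging*
with a sigmoid output, not the concatenation variant common elsewhere in
the GAT literature; both the single-sample reference and the batched
trainable model implement the averaged form and are tested for agreement
to 1e−10). Layers stack with a dense ReLU map between attention layers;
default depth 2, hidden width 16, 8 heads (the head-count sweep harness
scans {2, 4, 8, 16, 20}).

**Domain attention.** Spatial attention maps the raw feature block to an
n×n row-stochastic matrix via a bilinear form
`P_s ⊙ σ((X Q1) Q2 (Q3 Xᵀ) + Q_s)` followed by row softmax, with
Q1: (F, 1), Q2: (1, T), Q3: (T, F); an (n, F, T) time block is averaged
over T before the form (the window width survives as the inner dimension
of Q2/Q3). These shapes are a design choice — the inner dimensions are
arbitrary widths; what matters is that the product collapses the feature
axis to an n×n score matrix. The matrix right-multiplies the (features ×
nodes) output of the graph-attention stack, so each output node column is
a convex combination of node columns. Temporal attention mirrors this
exactly on the (T, H) hidden-state sequence with P1: (H, 1), P2: (1, m),
P3: (m, H), producing a T×T matrix applied to the (H, T) states. Row-wise
softmax is used in both cases because rows act as queries under
right-multiplication.

**GRU.** The update rule is implemented exactly as

```
u = σ(W_u x + U_u h + b_u),  d = σ(W_d x + U_d h + b_d)
ĥ = tanh(W_h x + U_h (d ⊙ h) + b_h),  h' = u ⊙ h + (1−u) ⊙ ĥ
```

— note the update gate multiplies the *previous* state, the mirror image
of the more common convention (equivalent up to the gate's sign; fixed
here and asserted by tests, including the convexity property that every
new coordinate lies between the previous state and the candidate). Hidden
size defaults to 32. The branch consumes channel-averaged features of a
5-epoch window centred on the scored epoch; a per-channel GRU with shared
weights is a possible extension but the channel-averaged form is the
default because the spatial branch already owns the channel axis.

**Fusion and transitional-stage estimator.** Both branch outputs are
average-pooled over their structural axis (nodes / time steps) and
concatenated. A fully connected layer plus softmax yields the stage
distribution P; the estimator computes a per-stage attention vector
`A = σ(FC(P))` (a 5→5 map over the probabilities alone) and the refined
score `f* = A ⊙ P`. `f*` is intentionally unnormalized — every entry is
strictly below the corresponding probability since σ < 1 — and the final
decision is `argmax f*` (ties toward the lower class index). Training
renormalizes `f*` and minimizes cross-entropy of the renormalized vector,
keeping the estimator inside the gradient path; when the estimator is
ablated the head is a plain FC + softmax.

**Differentiation and optimization.** The package trains on a small
tape-based reverse-mode autodiff engine over numpy (`mganet.autodiff`),
sufficient for the model's scale (~10⁴ parameters, ≤ 64-node graphs);
gradient correctness is tested against central finite differences.
Optimizer: Adam, learning rate 1e−3, batch 32, at most 100 passes,
early-stopped on validation loss with patience 10 and best-validation
parameters restored. All of these are this package's choices, exposed in
`TrainingConfig`. Training is deterministic given the seed: one seeded
generator drives initialisation, another drives batch order.

**Ablation switches.** A = GRU branch, B = both domain attentions,
C = estimator head; the stacked graph-attention spatial path is the
always-present baseline. The harness trains all eight combinations with a
shared seed and split and reports accuracy/MF1/kappa per variant; because
single trainings are stochastic, only the median-over-seeds full-model ≥
baseline comparison is asserted, not per-row orderings.

## Synthetic polysomnography

The generator provides the study conditions for every test.

* **Hypnogram**: first-order Markov chain started from its stationary
  distribution. Default transition matrix
  `P = 0.88 I + 0.12 · 1 πᵀ` with
  `π = (W 0.12, N1 0.075, N2 0.45, N3 0.13, REM 0.225)` — a rank-one
  construction whose stationary distribution is exactly π, giving N1 the
  5–10 % and REM the 20–25 % occupancy of a typical night while keeping
  every stage sticky (self-transition ≥ 0.889). The construction trades
  realistic transition *topology* (e.g. W rarely jumps straight to N3)
  for an exactly calibrated occupancy profile.
* **Signals**: per epoch, one sinusoid per band at a random in-band
  frequency (shared across channels), random phase per channel,
  stage-specific RMS amplitude, per-channel gain jitter
  `1 + N(0, 0.1)`, white noise sd 5 µV, 100 Hz sampling. Band amplitude
  defaults make W alpha-dominant, N1 theta, N2 sigma, N3 delta, REM
  theta+beta; N1 and REM share the theta emphasis so transitional
  confusion is present. A nearest-centroid rule on band features already
  exceeds 80 % accuracy by design — the task is solvable, so a training
  failure indicates a model defect, not an impossible task.
* One seeded generator per dataset drives the hypnogram and then each
  epoch's signal in order; identical configs reproduce identical data.

What the generator does **not** emulate: waveform morphology
(K-complexes, discrete spindles, eye-movement artifacts), 1/f background
spectra, inter-subject variability, electrode artifacts, and realistic
stage-sequence grammar. Passing tests therefore demonstrate pipeline and
model correctness on spectrally separable data, not clinical-grade
staging performance; benchmark numbers on clinical corpora are explicitly
out of scope.

## Problem sizes and numerical choices

Default experiments use 2000 epochs (≈ 16.7 h) on 6 channels; the
calibration checks use 10,000-epoch hypnograms; the ablation and sweep
harnesses run at the same scale with a shared seed. Softmaxes subtract the
row maximum before exponentiation (a constant shift, gradient-exact);
attention rows are asserted to sum to 1 within 1e−6; zero-variance
feature series are left centered rather than divided by zero; the
degenerate kappa case p_e = 1 is reported as 0. Context windows at
recording edges replicate the boundary epoch; windows near split
boundaries may therefore see a few epochs from the adjacent block, a
deliberate simplification of the contiguous-split protocol (clinical
protocols would split by subject, which has no analogue in a single
simulated recording).

## Known limitations

* The autodiff engine implements exactly the operations the model needs;
  it is not a general array framework and keeps whole batches in memory.
* The spatial attention time-block treatment (average over T before the
  bilinear form) discards within-window ordering; ordering information is
  the GRU's job.
* Metrics are computed from the package's own confusion-matrix code;
  scikit-learn serves as an independent cross-check in the test suite
  only.
* The sticky rank-one transition matrix calibrates occupancies exactly
  but simplifies transition structure; studies of transition *sequences*
  should supply their own matrix through `SimulationConfig`.
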