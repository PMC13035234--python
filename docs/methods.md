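# Methods

## Model

`phosphodyn` models time-resolved phosphoproteomics as a prior-knowledge-
constrained recurrent network.  A curated signed, directed interaction network
(nodes = proteins, edges = activating/inhibiting interactions, OmniPath-style)
fixes which recurrent weights may be nonzero.  With adjacency mask `A`,
trainable weights `W` (support(W) ⊆ support(A)), per-node bias `b` and a
constant perturbation input `x`, the node state evolves over `L` discrete
steps:

    h_0 = f(b + x),        h_{t+1} = f(W h_t + b + x)

The activation `f` is leaky-linear for negative pre-activations (slope
λ = 0.01), the identity on [0, 0.5], and saturates as `1 − 0.25/z` above 0.5 —
continuous, monotone, bounded by 1.  Ligand stimulation contributes `+1` and a
drug contributes `−5` at its annotated target node(s), each scaled by a
trainable nonnegative weight (softplus-reparameterized so the sign of the
perturbation can never invert).  The large negative drug input pushes the
target's activity smoothly toward zero through the leaky branch.

**Phosphosite mapping.**  Each measured site `GENE:RESIDUEposition` is
assigned to exactly one node.  A binary selection matrix gathers the assigned
node's trajectory (`h_site = h · P`); the scalar activity scales a trainable
5-dimensional per-site embedding (`S = h_site · E`); a single MLP shared by
all sites collapses each scaled embedding to a scalar intensity
(`ŷ = MLP(S)`).  The mask makes each site's prediction depend on its own
node only; the embedding direction lets the shared MLP give each site its own
(possibly non-monotone) response shape.  Two ablation variants exist:
`identity` (ŷ = h_site) and `scalar` (per-site affine map).

**Time mapping.**  Experimental minutes rarely coincide with recurrent steps.
One trainable anchor per observed time places it at a fractional step:

    u = L · sigmoid(u_raw)
    c = cumsum(softplus(δ_raw)),  c_norm = (c − c_1)/(c_K − c_1)
    anchors = u · g(α, c_norm),   anchors_1 := 0

with reweighting `g(α, c) = (e^{αc} − 1)/(e^{α} − 1)` (monotone, maps
[0,1]→[0,1], analytic α→0 limit `g = c`).  An alternative parenthesization,
`g(α, c) = (e^{αc} + 1)/(e^{α} + 1)`, is available via
`ModelConfig(eq5_variant="literal")`; it is not the default because it does
not pin g(α, 0) = 0 and collapses all anchors to `u` at α = 0.  Outputs at a
fractional step `m` are read by soft indexing,
`ŷ = (1 − Δm)·y_{⌊m⌋} + Δm·y_{⌈m⌉}` with `Δm = m − ⌊m⌋` — exact at integers,
piecewise linear and differentiable in between.  Anchors drifting past
`L − 1` are clamped (a float-precision guard; `u < L` by construction).

## Training

The objective is masked MSE over observed (sample, time, site) entries plus:
L2 on all parameters (λ = 1e−5), a mode-of-action penalty
`Σ relu(−sign·W)²` (weight 1.0), and a spectral penalty
`relu(ρ̂(W) − 0.95)²` (weight 10) where `ρ̂` is a 5-step power-iteration
estimate started from the fixed normalized all-ones vector (reproducible; no
random restarts; the penalty controls the estimate, which tracks the true
radius well for matrices with a real dominant eigenvalue).  Optimization is
Adam (lr 2e−3 default, 5000 epochs default) under cosine annealing with warm
restarts (period = epochs/5, floor = 1% of the base rate), with smooth
gradient clipping `g ← g_max·tanh(‖g‖/g_max)·g/‖g‖` (g_max = 10) and additive
Gaussian gradient noise of standard deviation `0.01 × current lr`.

Batching: the default mini-batch is one sample's full time series (preserving
temporal coherence); `batch_mode="full"` and `batch_mode="minibatch"`
(random groups of `batch_size` samples) are provided and are used by the
scaled-down evaluation protocols, where they converge equivalently at a
fraction of the wall time (verified on the drug-scaling protocol).

All forward/backward computations are NumPy; gradients (including
backpropagation through time, the time map, and the power iteration) are
analytic and pinned against finite differences in the test suite.  The
recurrent loops and the shared site MLP have compiled (numba) inner loops —
bit-identical to the NumPy reference paths, which remain as fallback; the
site MLP exploits ``(h·E_i)·W1 = h·(E_i·W1)`` so the layer is elementwise over
a precomputed ``E @ W1``.

## Synthetic data generator

The generator emulates the structure of an EGF-stimulation phosphoproteomics
experiment with single-target inhibitors:

- **Network**: random signed digraph with a designated receptor (default
  `EGFR`); a spanning out-tree guarantees every node is reachable from the
  receptor, extra random edges (≈1.5 per node, 30% inhibitory) add feedback
  and convergence, and every node keeps at least one outgoing edge so any node
  is a viable drug target.
- **Ground truth**: weight magnitudes log-uniform in [0.1, 1] on the support,
  sign-consistent with the network, rescaled so the spectral radius of |W|
  equals 0.8 (contractive, settling within the 150-step horizon); biases
  uniform in [0.05, 0.3], giving every node a positive basal activity, as
  basal phosphorylation does in cells — without it most nodes sit at zero or
  negative operating points and inhibiting them produces no measurable signal.
- **Sites**: per-node counts ~ round(Exponential(mean 2)); per-site scales
  log-uniform in [0.25, 4]; site value `y = log2(1 + scale · max(h, 0))` after
  dividing each node's trajectory by its cross-condition maximum (floored at
  1e−3 so fully inactive nodes stay at zero).
- **Design**: every sample receives constant ligand stimulation; each
  synthetic drug inhibits a single distinct node with the fixed −5 input; one
  stimulation-only control sample accompanies the drugged samples.
- **Sampling**: trajectories run 150 steps and are subsampled at
  t = 0, 1, 2, 3, 5, 8, 10, 15, 20, 50 minutes through a fixed concave
  generating map `m(t) = 149 · (t/50)^0.6` (the learned time map must recover
  whatever map generated the data); Gaussian replicate noise (sd 0.02 on the
  log2 scale — calibrated so that the noise ceiling of zero-shot differential
  correlations, i.e. what a perfect model could score, sits near 0.85,
  consistent with a well-performing model plateauing around 0.8) is added
  last.

What the generator does *not* emulate: mass-spectrometry missingness
mechanisms, batch effects, multi-target drugs, dose dependence, and the
heavy-tailed site-count and intensity distributions of real data.  Passing
the synthetic benchmarks therefore demonstrates that the architecture,
training and protocols work end to end on data of the right shape and
generative structure — not that real-data performance is guaranteed.

## Evaluation protocols and desk-scale study conditions

All performance numbers are Pearson correlations of *difference* trajectories:
t = 0-subtracted values for time-series tasks, stimulated-control-subtracted
values for drug tasks (pooled over sites × timepoints by default; a single
evaluation timepoint is available via `eval_time`).  A naive baseline predicts
a held-out drug as the mean response of the remaining drugs; bootstrap
comparison resamples phosphosites (the replication unit) with add-one
smoothing and half-weight ties.

The shipped protocols run at desk scale on one CPU:

- **Down-sampling interpolation** (`run_downsampling_protocol`): 40-node
  network, control + 5 drugs, observations at uniformly spaced steps within
  the first 30 recurrent steps (where the primary dynamics occur), time map
  fixed to those anchors, 5000 full-batch epochs (the standard training
  length; this stage is fit-limited, so it gets the full budget); scored on
  the withheld steps; 3 replicate seeds.
- **Drug-count scaling** (`run_drug_scaling_protocol`): 120-node network (the
  smallest supporting 101 distinct targets), leave-one-drug-out at training
  sizes 5/15/100 with 3/2/2 sampled folds × 3 replicate seeds; minibatch
  training (300/400/300 epochs — on few-sample zero-shot runs longer training
  degrades transfer by absorbing replicate noise, so these budgets are
  deliberately moderate).
- **Ablation ladder** (`run_ablation_protocol`): fixed-anchor + identity map
  baseline, + trainable time map, + per-site scalar map, + full embedding map,
  under sample-fold cross-validation.
- **Kinase–substrate inference** (`infer_kinase_substrates`): in-silico −5
  input at each kinase; predicted substrates are measured sites one directed
  edge downstream whose control-subtracted prediction at the last timepoint
  drops by ≥ 0.5 (configurable, always reported in the output); classification
  against a reference pair list restricted to measured sites.


## Numerical choices and degenerate inputs

- Power iteration uses a fixed start vector; a vanishing iterate returns
  radius 0.
- `prune_by_weight` keeps edges at exactly the threshold magnitude.
- Anchors: softplus underflow (all-equal cumulative offsets) raises a "flat
  offsets" error; the first anchor is a hard override to step 0, carrying no
  gradient.
- Reference-site anchor fitting scans a 0.01-step grid left-to-right under a
  monotonicity constraint; a flat reference trajectory (range < 1e−8) is an
  error — with a flat input, timing information is unrecoverable, and
  non-monotone references admit ambiguous anchors.
- Undefined correlations (zero-variance difference vectors) raise errors and
  are never silently reported as 0; near-zero-mean entries in seed-stability
  CVs are reported as missing.
- Checkpoints are versioned JSON (text-only, portable); phospho tables write
  with `%.17g` so write→read round trips are bit-exact.

## Known limitations

- The model predicts only sites present in training (no sequence-informed
  embeddings for unseen sites) and each site maps to exactly one node.
- The spectral penalty constrains a power-iteration estimate; for weight
  matrices whose dominant eigenvalue is complex, the true radius can exceed
  the estimate.
- Zero-shot transfer is fold-heterogeneous: drugs with a broad downstream
  response transfer at r ≈ 0.8–0.9, but a drug whose only measurable effect is
  on its own target's phosphosites forces the shared MLP to extrapolate into
  negative node activities never observed for those sites' embedding
  directions, and such folds can score near zero or anti-correlated.  The
  smaller the network relative to the drug panel, the larger the fraction of
  such own-site-only folds, so scaled-down mean correlations sit below what
  the same protocol yields on large, pretrained-style generators.
- With a shared MLP of fixed width, datasets whose site draw concentrates
  many sites on few nodes can hit a representational ceiling (training MSE
  plateaus above the noise floor regardless of epochs); width is configurable.
- Drug application is binary (no dose–response); dynamics are deterministic
  and discrete-time.
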