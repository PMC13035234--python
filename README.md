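# phosphodyn

Prior-knowledge-constrained recurrent modeling of time-resolved
phosphoproteomics.

Modern mass spectrometry measures thousands of phosphorylation sites over
time, but the tables are descriptive: they do not say how signaling would
evolve under a perturbation that was never measured.  `phosphodyn` couples a
curated signed protein-interaction network to a recurrent neural model so
that the data can be used predictively — interpolating unmeasured timepoints,
predicting the phosphoproteomic response to a drug seen only as a
(drug → target) annotation ("zero-shot"), and nominating kinase–substrate
relations by in-silico inhibition.  It is a library first (NumPy end to end,
analytic gradients), with a thin `phosphodyn` command-line layer and a
synthetic-data generator so every analysis runs without external downloads.

## Model

A signed, directed prior-knowledge network with adjacency mask `A` constrains
trainable interaction weights `W` (support(W) ⊆ support(A), with penalties for
contradicting the curated activation/inhibition signs and for a spectral
radius above 0.95).  Node states evolve over `L` discrete steps under constant
perturbation inputs (`+1` per applied ligand at its receptor, `−5` per applied
drug at its annotated target, both scaled by trainable nonnegative weights):

    h₀ = f(b + x),   h_{t+1} = f(W h_t + b + x)

with a bounded activation `f` that is leaky-linear for negative inputs.  Node
activities map to measured phosphosites `GENE:RESIDUEposition` through a
masked per-site embedding: `h_site = h·P`, `S = h_site·E`, `ŷ = MLP(S)`, where
`P` selects each site's single assigned node, `E` holds a trainable
5-dimensional embedding per site, and one shared MLP collapses each scaled
embedding to a scalar intensity.  A monotonic time map with one trainable
anchor per sampling time (`u = L·sigmoid(u_raw)`;
`anchors = u·(e^{α·c} − 1)/(e^{α} − 1)` on the normalized cumulative softplus
of raw offsets, first anchor pinned to step 0) aligns experimental minutes to
fractional recurrent steps, read out by soft indexing
`ŷ = (1−Δm)·y_{⌊m⌋} + Δm·y_{⌈m⌉}`.  Training minimizes masked MSE + L2 (1e−5)
+ sign and spectral penalties with Adam (lr 2e−3, cosine annealing with warm
restarts, smooth gradient clipping, decaying gradient noise).  See
`docs/methods.md` for the full account.

## Worked example

`examples/simulate_and_train.py` generates a 20-node synthetic EGF-style
experiment (a stimulated control plus three single-target inhibitors, sampled
at t = 0–50 min) and fits the full model:

```
$ python examples/simulate_and_train.py
dataset: 4 samples x 10 timepoints x 28 phosphosites
masked MSE: epoch 1 1.6471 -> epoch 400 0.0372
fit correlation across all entries: r = 0.951
learned anchors (fractional recurrent steps per sampling time):
  t =    0 min -> step   0.00
  t =    1 min -> step   7.23
  ...
  t =   50 min -> step  71.51
```

The masked MSE falling from 1.65 to 0.04 (on log2-intensity units whose
variance is ~0.5) means the recurrent dynamics, the site map and the time map
jointly reproduce the measured trajectories (r = 0.95 between all fitted and
observed entries); the anchors rise steeply over the early minutes and flatten
later, recovering the concave sampling of the generating process.  The other examples each demonstrate one capability and print what
the numbers mean:

- `examples/zero_shot_drug_prediction.py` — leave-one-drug-out prediction
  versus the naive mean-of-other-drugs baseline;
- `examples/timepoint_interpolation.py` — held-out-timepoint inference via
  linear interpolation, a reference-site anchor fit, or one-to-one step
  mapping;
- `examples/kinase_substrate_inference.py` — in-silico kinase inhibition
  classified against a reference pair list.

The CLI wraps the same functions for shell use, e.g.

```bash
phosphodyn simulate --seed 1 --out data/
phosphodyn train --config train.yaml --seed 0 --out run/
phosphodyn predict --checkpoint run/checkpoint.json --drugs D_N004 --out pred.tsv
phosphodyn prune --in omnipath.tsv --source EGFR --out pruned.tsv
```

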