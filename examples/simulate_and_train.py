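"""Generate a synthetic phosphoproteomic time course and fit the model.

Builds a 20-node signed network with a known ground-truth parameterization,
simulates a stimulated control plus three single-target drug samples at the
standard sampling grid, trains the composed model (recurrent core + site map +
time map), and prints the loss trajectory and the fit quality.
"""

import numpy as np

import phosphodyn as pdyn
from phosphodyn.model import ModelConfig, PhosphoModel
from phosphodyn.trainer import TrainingConfig, train

net = pdyn.make_random_network(n_nodes=20, seed=0)
gt = pdyn.sample_ground_truth(net, seed=0)
pdyn.assign_sites(gt, seed=0)
rng = np.random.default_rng(0)
targets = [str(t) for t in rng.choice(net.node_ids, size=3, replace=False)]
ds = pdyn.generate_timecourse(gt, targets, seed=0)
print(f"dataset: {ds.timecourse.n_samples} samples x "
      f"{ds.timecourse.times.size} timepoints x "
      f"{len(ds.site_assignment.site_ids)} phosphosites")

model = PhosphoModel(net, ds.site_assignment, ds.design, ds.timecourse.times,
                     ModelConfig(seed=0))
report = train(model, ds.timecourse, ds.design,
               TrainingConfig(epochs=400, batch_mode="full", random_seed=0))
print(f"masked MSE: epoch 1 {report.mse[0]:.4f} -> "
      f"epoch {len(report.mse)} {report.mse[-1]:.4f}")

preds = model.predict(ds.design)
r = np.corrcoef(preds.ravel(), ds.timecourse.values.ravel())[0, 1]
print(f"fit correlation across all entries: r = {r:.3f}")
print("learned anchors (fractional recurrent steps per sampling time):")
for t, a in zip(ds.timecourse.times, model.anchors()[0]):
    print(f"  t = {t:4.0f} min -> step {a:6.2f}")
# the anchors should rise steeply early and flatten late, mirroring the
# concave generating time map; a near-zero final MSE means the recurrent
# dynamics, site map and time map jointly reproduce the measurements
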