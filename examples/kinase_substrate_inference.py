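"""Infer kinase-substrate relations by in-silico kinase inhibition.

After training on a synthetic dataset, each kinase node receives the fixed
inhibitory input in silico; phosphosites that drop past a threshold and sit
one directed edge downstream of the kinase are called predicted substrates and
classified against a reference pair list (here: the generating network's true
direct edges, playing the role of a curated database).
"""

import numpy as np

import phosphodyn as pdyn
from phosphodyn import evalsuite
from phosphodyn.model import ModelConfig, PhosphoModel
from phosphodyn.trainer import TrainingConfig, train

net = pdyn.make_random_network(n_nodes=20, seed=3)
gt = pdyn.sample_ground_truth(net, seed=3)
pdyn.assign_sites(gt, seed=3)
rng = np.random.default_rng(3)
targets = [str(t) for t in rng.choice(net.node_ids, size=4, replace=False)]
ds = pdyn.generate_timecourse(gt, targets, seed=3)

model = PhosphoModel(net, ds.site_assignment, ds.design, ds.timecourse.times,
                     ModelConfig(seed=0))
train(model, ds.timecourse, ds.design,
      TrainingConfig(epochs=400, batch_mode="full", random_seed=0))

# reference: sites on each kinase's direct downstream neighbors
g = net.to_digraph()
reference = [(k, s) for k in net.node_ids
             for s in ds.site_assignment.site_ids
             if ds.site_assignment.site_to_node[s] in set(g.successors(k))]

kinases = [n for n in net.node_ids if g.out_degree(n) > 0][:6]
res = evalsuite.infer_kinase_substrates(model, kinases, reference,
                                        threshold=0.3)
print(f"downregulation threshold: {res.threshold}")
print(f"{'kinase':<8s} validated  predicted-only  database-only")
for k in kinases:
    print(f"{k:<8s} {len(res.validated[k]):9d}  {len(res.predicted_only[k]):14d}"
          f"  {len(res.database_only[k]):13d}")
# validated = predicted by the in-silico inhibition AND listed in the
# reference; database-only pairs are the false negatives (sites whose
# simulated response stayed above the threshold)
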