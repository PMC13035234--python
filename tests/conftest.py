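import numpy as np
import pytest

import phosphodyn as pdyn
from phosphodyn.model import ModelConfig, PhosphoModel
from phosphodyn.trainer import TrainingConfig


@pytest.fixture(scope="session")
def tiny_network():
    """A 4-node chain with a branch: R -> A -> B, R -> C (C inhibitory on B)."""
    edges = [("R", "A", 1), ("A", "B", 1), ("R", "C", 1), ("C", "B", -1)]
    return pdyn.pkn.network_from_edges(["A", "B", "C", "R"], edges)


@pytest.fixture(scope="session")
def small_dataset():
    """A 12-node synthetic dataset with 3 drugs (shared across tests)."""
    net = pdyn.make_random_network(n_nodes=12, seed=1)
    gt = pdyn.sample_ground_truth(net, seed=1)
    pdyn.assign_sites(gt, seed=1)
    rng = np.random.default_rng(2)
    targets = [str(t) for t in rng.choice(net.node_ids, size=3, replace=False)]
    return pdyn.generate_timecourse(gt, targets, seed=3)


@pytest.fixture()
def small_model(small_dataset):
    ds = small_dataset
    return PhosphoModel(ds.ground_truth.network, ds.site_assignment, ds.design,
                        ds.timecourse.times, ModelConfig(seed=0, n_steps=30))


@pytest.fixture(scope="session")
def quick_training_config():
    return TrainingConfig(epochs=60, batch_mode="full", random_seed=0)
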