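"""Synthetic phosphoproteomic time-series generation.

Datasets are generated from a known ground-truth signaling model so that every
other module can be benchmarked without external data: a signed random network
with a designated receptor, sign-consistent interaction weights rescaled to a
contractive spectral radius, exponentially distributed per-node phosphosite
counts with per-site scaling factors, a log2 site transform, single-target
drug inhibitions (input -5), constant ligand stimulation of the receptor in
every sample, recurrent trajectories over 150 steps, and subsampling at the
experimental grid t = 0, 1, 2, 3, 5, 8, 10, 15, 20, 50 minutes through a fixed
monotone generating time->step map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from . import rnn, time_map
from ._utils import rng_from_seed
from .io import PhosphoTimeCourse
from .pkn import SignedNetwork, network_from_edges, spectral_radius
from .rnn import PerturbationDesign
from .site_map import SiteAssignment

#: the experimental sampling grid emulated by default (minutes)
DEFAULT_TIMES = np.array([0.0, 1.0, 2.0, 3.0, 5.0, 8.0, 10.0, 15.0, 20.0, 50.0])

LIGAND = "EGF"


def make_random_network(n_nodes: int = 120, receptor: str = "EGFR",
                        extra_edges_per_node: float = 1.5,
                        p_inhibit: float = 0.3, seed: int = 0) -> SignedNetwork:
    """A random signed digraph in which every node is reachable from the receptor.

    A spanning out-tree from the receptor guarantees reachability; additional
    random edges (including feedback) raise the mean degree to a realistic
    signaling-network range; every node is given at least one outgoing edge so
    that inhibiting it can propagate.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = rng_from_seed(seed)
    others = [f"N{i:03d}" for i in range(n_nodes - 1)]
    node_ids = [receptor] + others
    edges: set[tuple[str, str]] = set()
    placed = [receptor]
    for node in others:
        parent = placed[int(rng.integers(len(placed)))]
        edges.add((parent, node))
        placed.append(node)
    n_extra = int(extra_edges_per_node * n_nodes)
    for _ in range(n_extra):
        u, v = rng.choice(node_ids, size=2, replace=False)
        edges.add((str(u), str(v)))
    for node in node_ids:  # every node can signal onward
        if not any(s == node for s, _ in edges):
            choices = [n for n in node_ids if n != node]
            edges.add((node, str(rng.choice(choices))))
    edge_list = sorted(edges)
    signs = rng.choice([-1, 1], size=len(edge_list),
                       p=[p_inhibit, 1.0 - p_inhibit])
    signed = [(s, t, int(sg)) for (s, t), sg in zip(edge_list, signs)]
    net = network_from_edges(sorted(node_ids), signed)
    net.receptor = receptor  # type: ignore[attr-defined]
    return net


@dataclass
class SyntheticGroundTruth:
    """The generating model, retained for parameter-recovery tests."""

    network: SignedNetwork
    weights: np.ndarray
    bias: np.ndarray
    receptor: str
    spectral_target: float
    seed: int
    sites: SiteAssignment | None = None
    site_scales: dict[str, float] = field(default_factory=dict)
    site_counts: dict[str, int] = field(default_factory=dict)
    noise_sd: float = 0.02

    def states_for_design(self, design: PerturbationDesign,
                          n_steps: int) -> np.ndarray:
        x = rnn.build_inputs(design, self.network.node_ids, {}, {})
        return rnn.simulate(self.weights, self.bias, x, n_steps)


def sample_ground_truth(network: SignedNetwork, spectral_target: float = 0.8,
                        seed: int = 0) -> SyntheticGroundTruth:
    """Sample sign-consistent weights and rescale to a contractive radius.

    Weight magnitudes are log-uniform in [0.1, 1] on the network support, then
    rescaled so the spectral radius of the magnitude matrix equals the target
    (< 1).  Biases are uniform in [0.05, 0.3], giving every node a positive
    basal activity — as in real signaling, where basal phosphorylation keeps
    nodes in a responsive operating range, so that inhibiting any node has a
    measurable effect on its own and downstream sites.  Deterministic under
    the seed.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    rng = rng_from_seed(seed)
    n = network.n_nodes
    mags = np.exp(rng.uniform(np.log(0.1), np.log(1.0), size=(n, n)))
    W = mags * network.sign_matrix * network.adjacency_mask
    rho = spectral_radius(np.abs(W), n_iter=200)
    if rho > 0:
        W *= spectral_target / rho
    bias = rng.uniform(0.05, 0.3, size=n)
    receptor = getattr(network, "receptor", network.node_ids[0])
    return SyntheticGroundTruth(network=network, weights=W, bias=bias,
                                receptor=receptor,
                                spectral_target=spectral_target, seed=seed)


def assign_sites(gt: SyntheticGroundTruth, mean_sites: float = 2.0,
                 scale_range: tuple[float, float] = (0.25, 4.0),
                 seed: int = 0) -> SiteAssignment:
    """Sample per-node site counts and per-site scaling factors.

    Counts are round(Exponential(mean)); each site ``NODE:S<k>`` carries a
    log-uniform positive scale used by the site transform.
    """
    rng = rng_from_seed(seed)
    site_ids: list[str] = []
    site_to_node: dict[str, str] = {}
    scales: dict[str, float] = {}
    counts: dict[str, int] = {}
    for node in gt.network.node_ids:
        k = int(np.round(rng.exponential(mean_sites)))
        counts[node] = k
        for j in range(k):
            sid = f"{node}:S{j + 1}"
            site_ids.append(sid)
            site_to_node[sid] = node
            scales[sid] = float(np.exp(rng.uniform(np.log(scale_range[0]),
                                                   np.log(scale_range[1]))))
    if not site_ids:
        raise ValueError("no sites generated: all per-node counts were zero")
    gt.sites = SiteAssignment(site_ids, site_to_node)
    gt.site_scales = scales
    gt.site_counts = counts
    return gt.sites


def site_transform(h: np.ndarray, scale: float | np.ndarray) -> np.ndarray:
    """log2(1 + scale * max(h, 0)): nonnegative node activity to log2 intensity."""
    return np.log2(1.0 + scale * np.maximum(h, 0.0))


def generating_anchor_map(times: np.ndarray, n_steps: int,
                          exponent: float = 0.6) -> np.ndarray:
    """The fixed, monotone concave time->step map used to subsample trajectories.

    Minute 0 maps to step 0 and the last sampled minute to the last step;
    intermediate times follow a power law (early dynamics densely resolved).
    The learned time map is meant to recover this mapping from data.
    """
    times = np.asarray(times, dtype=float)
    return (n_steps - 1) * (times / times.max()) ** exponent


def build_design(drug_target_nodes: list[str], receptor: str,
                 control_id: str = "control") -> PerturbationDesign:
    """One stimulation-only control plus one stimulated sample per drug."""
    drugs = [f"D_{node}" for node in drug_target_nodes]
    sample_ids = [control_id] + [f"{d}_sample" for d in drugs]
    S = len(sample_ids)
    lmat = np.ones((S, 1))  # constant ligand stimulation everywhere
    dmat = np.zeros((S, len(drugs)))
    for j in range(len(drugs)):
        dmat[j + 1, j] = 1.0
    return PerturbationDesign(
        sample_ids=sample_ids, ligands=[LIGAND], drugs=drugs,
        ligand_matrix=lmat, drug_matrix=dmat,
        drug_targets={d: [node] for d, node in zip(drugs, drug_target_nodes)},
        ligand_receptors={LIGAND: [receptor]},
    )


@dataclass
class SyntheticDataset:
    """A generated benchmark dataset plus its generating model."""

    design: PerturbationDesign
    timecourse: PhosphoTimeCourse
    long_table: pd.DataFrame
    site_assignment: SiteAssignment
    ground_truth: SyntheticGroundTruth
    node_scale: np.ndarray
    metadata: dict

    def noiseless_site_values(self, steps: np.ndarray | None = None) -> np.ndarray:
        """Ground-truth site values at integer steps for this design, (S, T, I)."""
        gt = self.ground_truth
        n_steps = int(self.metadata["n_steps"])
        H = gt.states_for_design(self.design, n_steps)
        if steps is not None:
            H = H[:, np.asarray(steps, dtype=int), :]
        return _sites_from_states(H, gt, self.site_assignment, self.node_scale)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .pkn import write_network
        write_network(self.ground_truth.network, outdir / "network.tsv")
        # %.17g keeps the write -> read round trip bit-exact
        self.long_table.to_csv(outdir / "phospho.tsv", sep="\t", index=False,
                               float_format="%.17g")
        pio.write_site_assignment(self.site_assignment, outdir / "sites.tsv")
        pio.write_design(self.design, outdir / "design.tsv",
                         outdir / "drug_targets.tsv",
                         outdir / "ligand_receptors.tsv")
        with open(outdir / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2)


def _sites_from_states(H: np.ndarray, gt: SyntheticGroundTruth,
                       assignment: SiteAssignment,
                       node_scale: np.ndarray) -> np.ndarray:
    node_index = assignment.node_indices(gt.network.node_ids)
    hn = H / node_scale  # per-node cross-condition max normalization
    hs = hn[:, :, node_index]
    scales = np.array([gt.site_scales[s] for s in assignment.site_ids])
    return site_transform(hs, scales)


def generate_timecourse(gt: SyntheticGroundTruth,
                        drug_target_nodes: list[str],
                        n_steps: int = 150,
                        times: np.ndarray = DEFAULT_TIMES,
                        noise_sd: float | None = None,
                        n_replicates: int = 1,
                        time_exponent: float = 0.6,
                        seed: int = 0) -> SyntheticDataset:
    """Simulate, subsample and noise a full synthetic dataset.

    One stimulation-only control sample plus one per requested drug; each drug
    inhibits its single target node with the fixed -5 input.
    """
    if gt.sites is None:
        raise ValueError("call assign_sites before generate_timecourse")
    unknown = [n for n in drug_target_nodes if n not in gt.network.node_ids]
    if unknown:
        raise KeyError(f"unknown drug target node(s): {unknown}")
    noise_sd = gt.noise_sd if noise_sd is None else noise_sd
    rng = rng_from_seed(seed)
    design = build_design(drug_target_nodes, gt.receptor)
    times = np.asarray(times, dtype=float)
    H = gt.states_for_design(design, n_steps)
    node_scale = np.maximum(H.max(axis=(0, 1)), 1e-3)  # keep inactive nodes at zero
    anchors = generating_anchor_map(times, n_steps, time_exponent)
    H_t = time_map.soft_index(H, anchors, axis=1)
    Y = _sites_from_states(H_t, gt, gt.sites, node_scale)
    rows = []
    for rep in range(1, n_replicates + 1):
        noisy = Y + rng.normal(0.0, noise_sd, size=Y.shape) if noise_sd > 0 else Y
        for i, s in enumerate(design.sample_ids):
            for k, t in enumerate(times):
                for j, site in enumerate(gt.sites.site_ids):
                    rows.append((s, float(t), site, float(noisy[i, k, j]), rep))
    long_table = pd.DataFrame(rows, columns=pio.LONG_COLUMNS)
    tc = PhosphoTimeCourse.from_long_frame(long_table)
    tc = tc.subset_samples(design.sample_ids)  # keep design sample order
    tc = tc.subset_sites(gt.sites.site_ids)
    metadata = {
        "seed": seed, "ground_truth_seed": gt.seed,
        "spectral_target": gt.spectral_target,
        "n_steps": n_steps, "times": times.tolist(),
        "noise_sd": noise_sd, "n_replicates": n_replicates,
        "generating_time_map": {"form": "(L-1)*(t/t_max)^p",
                                "exponent": time_exponent},
        "drug_target_nodes": list(drug_target_nodes),
    }
    return SyntheticDataset(design=design, timecourse=tc, long_table=long_table,
                            site_assignment=gt.sites, ground_truth=gt,
                            node_scale=node_scale, metadata=metadata)


def shuffle_labels(ds: SyntheticDataset, seed: int = 0) -> SyntheticDataset:
    """Permute the sample -> measurement association (the design is unchanged).

    The identity permutation is excluded whenever another one exists, and the
    permutation used is recorded in the metadata.
    """
    S = ds.timecourse.n_samples
    if S < 2:
        raise ValueError("need at least 2 samples to shuffle labels")
    rng = rng_from_seed(seed)
    perm = rng.permutation(S)
    while S > 1 and np.array_equal(perm, np.arange(S)):
        perm = rng.permutation(S)
    tc = PhosphoTimeCourse(ds.timecourse.values[perm], ds.timecourse.mask[perm],
                           list(ds.timecourse.sample_ids),
                           ds.timecourse.times.copy(),
                           list(ds.timecourse.site_ids))
    metadata = dict(ds.metadata)
    metadata["label_permutation"] = perm.tolist()
    return SyntheticDataset(design=ds.design, timecourse=tc,
                            long_table=ds.long_table,
                            site_assignment=ds.site_assignment,
                            ground_truth=ds.ground_truth,
                            node_scale=ds.node_scale, metadata=metadata)
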