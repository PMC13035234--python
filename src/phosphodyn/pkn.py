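"""Signed directed prior-knowledge networks (PKN).

The scaffold of the recurrent signaling model is a curated network of signed,
directed protein–protein interactions (OmniPath-style edge lists).  This module
reads such networks, prunes them to the signaling cone downstream of a stimulus
receptor, analyzes trained edge weights, and provides the differentiable
power-iteration estimate of the spectral radius used to keep the recurrent
dynamics contractive.

Matrix orientation: ``adjacency_mask[t, s] == 1`` iff there is an edge
source ``s`` → target ``t``, so that a weight matrix ``W`` with the same
support propagates state by ``W @ h``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sign tokens accepted in edge-list files
SIGN_TOKENS = {
    "1": 1, "+1": 1, "-1": -1, "−1": -1,
    "activation": 1, "inhibition": -1, "stimulation": 1,
}

UNREACHABLE = -1  # sentinel hop count for shortest_signaling_distance


@dataclass
class SignedNetwork:
    """A signed directed interaction network.

    Attributes
    ----------
    node_ids
        Ordered, unique protein identifiers.
    edges
        List of ``(source, target, sign)`` with sign in {+1, -1}.
    adjacency_mask
        node x node binary matrix; ``[t, s] == 1`` iff edge s -> t exists.
    sign_matrix
        node x node matrix in {-1, 0, +1}, nonzero exactly on the mask support.
    """

    node_ids: list[str]
    edges: list[tuple[str, str, int]]
    adjacency_mask: np.ndarray = field(repr=False)
    sign_matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        nodes = set(self.node_ids)
        for s, t, sg in self.edges:
            if s not in nodes or t not in nodes:
                raise ValueError(f"edge endpoint not in node_ids: {s}->{t}")
            if sg not in (-1, 1):
                raise ValueError(f"edge sign must be +/-1, got {sg}")
        if not np.array_equal(self.adjacency_mask != 0, self.sign_matrix != 0):
            raise ValueError("sign_matrix support must equal adjacency_mask support")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, node: str) -> int:
        try:
            return self.node_ids.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_ids)
        for s, t, sg in self.edges:
            g.add_edge(s, t, sign=sg)
        return g

    def summary(self) -> dict:
        n_act = sum(1 for _, _, sg in self.edges if sg == 1)
        n_self = sum(1 for s, t, _ in self.edges if s == t)
        if n_self:
            logger.info("network contains %d self-loop(s) (autoregulation)", n_self)
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_activating": n_act,
            "n_inhibiting": self.n_edges - n_act,
            "n_self_loops": n_self,
        }

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


@dataclass
class TrainedNetwork:
    """A :class:`SignedNetwork` plus a trained weight matrix on its support."""

    base: SignedNetwork
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = self.base.n_nodes
        if w.shape != (n, n):
            raise ValueError("weights shape must match network")
        off_support = w[self.base.adjacency_mask == 0]
        if off_support.size and np.any(off_support != 0):
            raise ValueError("weights nonzero outside the adjacency mask")
        self.weights = w


def network_from_edges(node_ids: list[str],
                       edges: list[tuple[str, str, int]]) -> SignedNetwork:
    """Build the mask/sign matrices from an edge list."""
    idx = {n: i for i, n in enumerate(node_ids)}
    n = len(node_ids)
    mask = np.zeros((n, n), dtype=np.int8)
    signs = np.zeros((n, n), dtype=np.int8)
    for s, t, sg in edges:
        mask[idx[t], idx[s]] = 1
        signs[idx[t], idx[s]] = sg
    return SignedNetwork(node_ids, edges, mask, signs)


def read_network(path, dialect: dict[str, str] | None = None) -> SignedNetwork:
    """Read a signed edge list (TSV) into a :class:`SignedNetwork`.

    Parameters
    ----------
    path
        Tab-separated file with at least source/target/sign columns.
    dialect
        Optional column-name map with keys ``source``, ``target``, ``sign``.

    Nodes are ordered by sorted identifier; exact duplicate edges are
    collapsed, duplicates with conflicting signs are rejected.
    """
    cols = {"source": "source", "target": "target", "sign": "sign"}
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in edge list: {missing}")
    if len(df) == 0:
        raise ValueError("no edges in edge-list file")

    seen: dict[tuple[str, str], int] = {}
    for _, row in df.iterrows():
        s = str(row[cols["source"]])
        t = str(row[cols["target"]])
        tok = str(row[cols["sign"]]).strip().lower()
        if tok not in SIGN_TOKENS:
            raise ValueError(f"unmappable sign token {tok!r} on edge {s}->{t}")
        sg = SIGN_TOKENS[tok]
        key = (s, t)
        if key in seen:
            if seen[key] != sg:
                raise ValueError(f"conflicting duplicate edge {s}->{t} "
                                 "with opposite signs")
            continue
        seen[key] = sg

    node_ids = sorted({n for pair in seen for n in pair})
    edges = [(s, t, sg) for (s, t), sg in seen.items()]
    return network_from_edges(node_ids, edges)


def write_network(net: SignedNetwork, path) -> None:
    df = pd.DataFrame(net.edges, columns=["source", "target", "sign"])
    df.to_csv(path, sep="\t", index=False)


def prune_reachable(net: SignedNetwork, source: str) -> SignedNetwork:
    """Induced subnetwork on the source node plus all nodes reachable from it.

    Restricting the network to the signaling cone downstream of the stimulated
    receptor removes nodes that would otherwise sit at constant activity and
    explain no variance.
    """
    if source not in net.node_ids:
        raise KeyError(f"unknown source node {source!r}")
    g = net.to_digraph()
    keep = {source} | nx.descendants(g, source)
    node_ids = [n for n in net.node_ids if n in keep]  # preserve order
    edges = [(s, t, sg) for s, t, sg in net.edges if s in keep and t in keep]
    pruned = network_from_edges(node_ids, edges)
    logger.info("reachability pruning: %d -> %d nodes", net.n_nodes, pruned.n_nodes)
    return pruned


def prune_by_weight(tnet: TrainedNetwork, threshold: float = 0.1) -> TrainedNetwork:
    """Drop trained edges with |weight| strictly below ``threshold``.

    Edges at exactly the threshold magnitude are kept.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    base = tnet.base
    idx = {n: i for i, n in enumerate(base.node_ids)}
    edges = []
    for s, t, sg in base.edges:
        if abs(tnet.weights[idx[t], idx[s]]) >= threshold:
            edges.append((s, t, sg))
    new_base = network_from_edges(base.node_ids, edges)
    new_w = tnet.weights * new_base.adjacency_mask
    return TrainedNetwork(new_base, new_w)


def shortest_signaling_distance(net: SignedNetwork, source: str, target: str) -> int:
    """Minimum number of directed edges from ``source`` to ``target``.

    Returns :data:`UNREACHABLE` (-1) when no directed path exists.
    """
    for node in (source, target):
        if node not in net.node_ids:
            raise KeyError(f"unknown node {node!r}")
    g = net.to_digraph()
    try:
        return int(nx.shortest_path_length(g, source, target))
    except nx.NetworkXNoPath:
        return UNREACHABLE


def spectral_radius(W: np.ndarray, n_iter: int = 5) -> float:
    """Power-iteration estimate of the dominant eigenvalue magnitude.

    Starts from the fixed, normalized all-ones vector so estimates are
    reproducible (no random restarts).  Differentiable counterpart:
    :func:`spectral_radius_with_grad`.
    """
    rho, _ = _power_iteration(np.asarray(W, dtype=float), n_iter, want_grad=False)
    return rho


def spectral_radius_with_grad(W: np.ndarray, n_iter: int = 5) -> tuple[float, np.ndarray]:
    """Spectral-radius estimate and its gradient with respect to ``W``."""
    return _power_iteration(np.asarray(W, dtype=float), n_iter, want_grad=True)


def _power_iteration(W: np.ndarray, n_iter: int, want_grad: bool):
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be a square matrix")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n = W.shape[0]
    if n == 0:
        return 0.0, np.zeros_like(W)
    v = np.ones(n) / np.sqrt(n)
    vs = [v]
    a_list, n_list = [], []
    for k in range(n_iter):
        a = W @ v
        na = float(np.linalg.norm(a))
        if na < 1e-300:  # dynamics annihilate the iterate; radius estimate 0
            return 0.0, np.zeros_like(W)
        a_list.append(a)
        n_list.append(na)
        v = a / na
        vs.append(v)
    rho = n_list[-1]
    if not want_grad:
        return rho, None
    # reverse pass through a_k = W v_k, v_{k+1} = a_k / |a_k|, rho = |a_{K-1}|
    gW = np.zeros_like(W)
    da = a_list[-1] / n_list[-1]
    gW += np.outer(da, vs[n_iter - 1])
    gv = W.T @ da
    for k in range(n_iter - 2, -1, -1):
        a, na = a_list[k], n_list[k]
        da = gv / na - a * (a @ gv) / na**3
        gW += np.outer(da, vs[k])
        gv = W.T @ da
    return rho, gW
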