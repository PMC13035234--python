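"""Mapping signaling-node activity to measured phosphosite intensities.

Each phosphosite (identifier ``GENE:RESIDUEposition``, e.g. ``FOXO3:S7``) is
assigned to exactly one signaling node.  A binary selection matrix gathers the
assigned node's trajectory for every site; that scalar scales a per-site
trainable embedding vector (default 5 dimensions); a multilayer perceptron
shared across all sites collapses the scaled embedding back to a scalar
intensity.  The selection mask guarantees that a site's prediction depends on
no node other than its own.

Two ablation variants of the node->site relation are provided: ``identity``
(the raw gathered activity) and ``scalar`` (a per-site affine map).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_MAP_MODES = ("embedding", "scalar", "identity")


@dataclass
class SiteAssignment:
    """Ordered phosphosites and their one-to-one node assignments."""

    site_ids: list[str]
    site_to_node: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.site_ids if s not in self.site_to_node]
        if missing:
            raise ValueError(f"sites without node assignment: {missing[:5]}")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def node_indices(self, node_ids: list[str]) -> np.ndarray:
        """Index of each site's node in ``node_ids`` (the gather index)."""
        idx = {n: i for i, n in enumerate(node_ids)}
        out = np.empty(self.n_sites, dtype=int)
        for i, s in enumerate(self.site_ids):
            node = self.site_to_node[s]
            if node not in idx:
                raise KeyError(f"site {s!r} assigned to unknown node {node!r}")
            out[i] = idx[node]
        return out

    def selection_matrix(self, node_ids: list[str]) -> np.ndarray:
        """Binary node x site matrix P with exactly one nonzero per column."""
        P = np.zeros((len(node_ids), self.n_sites))
        P[self.node_indices(node_ids), np.arange(self.n_sites)] = 1.0
        return P

    def restrict_to_nodes(self, node_ids: list[str]) -> "SiteAssignment":
        """Drop sites whose protein has no node in the network (logged)."""
        nodes = set(node_ids)
        kept = [s for s in self.site_ids if self.site_to_node[s] in nodes]
        dropped = self.n_sites - len(kept)
        if dropped:
            logger.info("excluding %d site(s) without a network node", dropped)
        return SiteAssignment(kept, {s: self.site_to_node[s] for s in kept})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site_id": self.site_ids,
                             "node_id": [self.site_to_node[s] for s in self.site_ids]})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SiteAssignment":
        sites = [str(s) for s in df["site_id"]]
        return cls(sites, dict(zip(sites, (str(n) for n in df["node_id"]))))


def map_nodes_to_sites(h: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Gather each site's assigned-node trajectory: ``h_site = h . P``.

    ``h`` has nodes on its last axis; ``P`` is the node x site selection
    matrix.  A pure gather: no mixing across nodes.
    """
    if h.shape[-1] != P.shape[0]:
        raise ValueError("node dimension of h must match rows of P")
    return h @ P


def embed(h_site: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Scale each site's embedding vector by its raw input (scalar * vector)."""
    if E.ndim != 2 or E.shape[0] != h_site.shape[-1]:
        raise ValueError("E must be (n_sites, d) aligned with h_site's last axis")
    return h_site[..., None] * E


def site_intensity(S: np.ndarray, mlp: "SiteMLP") -> np.ndarray:
    """Collapse scaled embeddings to per-site scalar intensities via the MLP."""
    return mlp.forward(S)[0]


class SiteMLP:
    """One-hidden-layer perceptron shared across all phosphosites.

    tanh hidden nonlinearity, linear scalar output.  One hidden layer is
    enough to represent smooth monotone and non-monotone node->site relations
    (cosine, polynomial, sigmoid, square root); the default width (32) leaves
    headroom for the layer to give many sites distinct response shapes through
    their embedding directions.
    """

    def __init__(self, in_dim: int = 5, hidden: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(in_dim), size=(in_dim, hidden))
        self.b1 = np.zeros(hidden)
        self.w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=hidden)
        self.b2 = np.zeros(1)

    @property
    def in_dim(self) -> int:
        return self.W1.shape[0]

    def forward(self, S: np.ndarray):
        """Return per-site scalar outputs and the cache for backprop."""
        if S.shape[-1] != self.in_dim:
            raise ValueError(
                f"embedding width {S.shape[-1]} != MLP input width {self.in_dim}")
        A1 = S @ self.W1 + self.b1
        G = np.tanh(A1)
        y = G @ self.w2 + self.b2[0]
        return y, (S, G)

    def backward(self, cache, dy: np.ndarray):
        """Gradients of the parameters and of the input embeddings."""
        S, G = cache
        dG = dy[..., None] * self.w2
        dw2 = (G * dy[..., None]).reshape(-1, G.shape[-1]).sum(axis=0)
        db2 = np.array([dy.sum()])
        dA1 = dG * (1.0 - G**2)
        dW1 = S.reshape(-1, S.shape[-1]).T @ dA1.reshape(-1, dA1.shape[-1])
        db1 = dA1.reshape(-1, dA1.shape[-1]).sum(axis=0)
        dS = dA1 @ self.W1.T
        return {"W1": dW1, "b1": db1, "w2": dw2, "b2": db2}, dS
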