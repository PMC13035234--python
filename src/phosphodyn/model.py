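"""The composed model: recurrent core -> phosphosite map -> time map.

A :class:`PhosphoModel` owns every trainable parameter — the mask-constrained
interaction weights, per-node biases, nonnegative ligand/drug input scales,
per-site embeddings with the shared MLP (or the scalar/identity ablation
variants), and the monotonic time-map parameters — and provides the forward
pass to predicted site intensities at experimental times together with the
exact reverse-mode gradients used by the trainer.

Gradients are computed analytically (backpropagation through time for the
recurrent core); their correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import rnn, site_map, time_map
from ._utils import check_finite, inv_softplus, rng_from_seed, sigmoid, softplus

try:  # compiled site-map kernels; SiteMLP is the reference path
    from . import _kernels
except ImportError:  # pragma: no cover
    _kernels = None
from .pkn import SignedNetwork, network_from_edges
from .rnn import PerturbationDesign
from .site_map import SiteAssignment, SiteMLP

CHECKPOINT_SCHEMA_VERSION = 1


@dataclass
class ModelConfig:
    """Structural hyperparameters of the composed model."""

    n_steps: int = 150
    site_map_mode: str = "embedding"  # embedding | scalar | identity
    embed_dim: int = 5
    hidden_width: int = 32
    time_map_mode: str = "trainable"  # trainable | fixed
    eq5_variant: str = "shifted"
    no_pkn: bool = False
    seed: int = 0
    dtype: str = "float64"  # float32 halves memory traffic for large runs

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class PhosphoModel:
    """Prior-knowledge-constrained recurrent model of phosphosite dynamics."""

    def __init__(self, network: SignedNetwork, sites: SiteAssignment,
                 design: PerturbationDesign, times: np.ndarray,
                 config: ModelConfig | None = None,
                 fixed_anchors: np.ndarray | None = None):
        cfg = config or ModelConfig()
        if cfg.site_map_mode not in site_map.SITE_MAP_MODES:
            raise ValueError(f"unknown site_map_mode {cfg.site_map_mode!r}")
        design.validate_against(network.node_ids)
        self.network = network
        self.sites = sites.restrict_to_nodes(network.node_ids)
        self.design_space = design
        self.times = np.asarray(times, dtype=float)
        self.config = cfg
        n = network.n_nodes
        dtype = np.dtype(cfg.dtype)
        self.mask = (np.ones((n, n), dtype=dtype) if cfg.no_pkn
                     else network.adjacency_mask.astype(dtype))
        self.sign_matrix = (np.zeros((n, n), dtype=dtype) if cfg.no_pkn
                            else network.sign_matrix.astype(dtype))
        self.node_index = self.sites.node_indices(network.node_ids)
        self.P = self.sites.selection_matrix(network.node_ids).astype(dtype)
        # (perturbation, node) pairs carrying trainable nonnegative scales
        node_pos = {nd: i for i, nd in enumerate(network.node_ids)}
        self.lig_pairs = [(j, node_pos[r]) for j, l in enumerate(design.ligands)
                          for r in design.ligand_receptors[l] if r in node_pos]
        self.drug_pairs = [(j, node_pos[t]) for j, d in enumerate(design.drugs)
                           for t in design.drug_targets[d] if t in node_pos]
        if cfg.time_map_mode == "fixed":
            if fixed_anchors is None:
                raise ValueError("fixed time map requires fixed_anchors")
            fixed_anchors = np.asarray(fixed_anchors, dtype=float)
            if fixed_anchors.size != self.times.size:
                raise ValueError("one anchor per timepoint required")
            self.fixed_anchors = fixed_anchors
        else:
            self.fixed_anchors = None
        self.params = self._init_params()

    # ------------------------------------------------------------------
    # parameters
    # ------------------------------------------------------------------

    def _init_params(self) -> dict[str, np.ndarray]:
        cfg = self.config
        rng = rng_from_seed(cfg.seed)
        n = self.network.n_nodes
        # sign-consistent weights on the mask support, contractive at init
        mags = rng.uniform(0.05, 0.2, size=(n, n))
        signs = np.where(self.sign_matrix != 0, self.sign_matrix,
                         rng.choice([-1.0, 1.0], size=(n, n)))
        W = mags * signs * self.mask
        from .pkn import spectral_radius
        rho = spectral_radius(np.abs(W), n_iter=50)
        if rho > 0:
            W *= 0.6 / rho
        p: dict[str, np.ndarray] = {
            "W": W,
            "b": rng.normal(0.0, 0.01, size=n),
            "lig_raw": np.full(len(self.lig_pairs), inv_softplus(1.0)),
            "drug_raw": np.full(len(self.drug_pairs), inv_softplus(1.0)),
        }
        I = self.sites.n_sites
        if cfg.site_map_mode == "embedding":
            mlp = SiteMLP(cfg.embed_dim, cfg.hidden_width, rng)
            p.update({
                "E": rng.normal(0.0, 0.1, size=(I, cfg.embed_dim)),
                "mlp_W1": mlp.W1, "mlp_b1": mlp.b1,
                "mlp_w2": mlp.w2, "mlp_b2": mlp.b2,
            })
        elif cfg.site_map_mode == "scalar":
            p.update({"site_a": np.ones(I), "site_b": np.zeros(I)})
        if cfg.time_map_mode == "trainable":
            p.update({
                "delta_raw": np.zeros(self.times.size),
                "u_raw": np.zeros(1),
                "alpha": np.zeros(1),
            })
        dtype = np.dtype(cfg.dtype)
        return {k: v.astype(dtype) for k, v in p.items()}

    @property
    def n_trainable(self) -> int:
        masked = int(self.mask.sum()) if "W" in self.params else 0
        total = masked
        for k, v in self.params.items():
            if k != "W":
                total += v.size
        return total

    @property
    def has_sign_prior(self) -> bool:
        return not self.config.no_pkn

    def effective_weights(self) -> np.ndarray:
        """The mask is enforced multiplicatively: off-support entries never act."""
        return self.params["W"] * self.mask

    def _mlp(self) -> SiteMLP:
        mlp = SiteMLP.__new__(SiteMLP)
        mlp.W1 = self.params["mlp_W1"]
        mlp.b1 = self.params["mlp_b1"]
        mlp.w2 = self.params["mlp_w2"]
        mlp.b2 = self.params["mlp_b2"]
        return mlp

    # ------------------------------------------------------------------
    # forward
    # ------------------------------------------------------------------

    def build_inputs(self, design: PerturbationDesign | None = None) -> np.ndarray:
        """Constant per-sample per-node input vectors from the design."""
        design = design or self.design_space
        unknown = [d for d in design.drugs if d not in self.design_space.drugs]
        if unknown:
            raise KeyError(f"unknown drug(s) {unknown}; known drugs: "
                           f"{self.design_space.drugs}")
        unknown = [l for l in design.ligands if l not in self.design_space.ligands]
        if unknown:
            raise KeyError(f"unknown ligand(s) {unknown}; known ligands: "
                           f"{self.design_space.ligands}")
        n = self.network.n_nodes
        x = np.zeros((design.n_samples, n), dtype=self.params["W"].dtype)
        lw = softplus(self.params["lig_raw"])
        dw = softplus(self.params["drug_raw"])
        lig_col = {l: j for j, l in enumerate(design.ligands)}
        drug_col = {d: j for j, d in enumerate(design.drugs)}
        for p, (j_full, node) in enumerate(self.lig_pairs):
            lig = self.design_space.ligands[j_full]
            if lig in lig_col:
                x[:, node] += (design.ligand_matrix[:, lig_col[lig]]
                               * rnn.LIGAND_INPUT * lw[p])
        for p, (j_full, node) in enumerate(self.drug_pairs):
            drug = self.design_space.drugs[j_full]
            if drug in drug_col:
                x[:, node] += (design.drug_matrix[:, drug_col[drug]]
                               * rnn.DRUG_INPUT * dw[p])
        return x

    def anchors(self):
        """Current anchors and, in trainable mode, the backward cache."""
        L = self.config.n_steps
        if self.config.time_map_mode == "fixed":
            return self.fixed_anchors, None
        u = time_map.compute_upper_bound(float(self.params["u_raw"][0]), L)
        anchors, cache = time_map.compute_anchors(
            self.params["delta_raw"], float(self.params["alpha"][0]), u,
            self.config.eq5_variant, return_cache=True)
        return anchors, cache

    def _site_outputs(self, H_sel: np.ndarray):
        """Site intensities at the selected steps, plus the backward cache."""
        hs = H_sel[:, :, self.node_index]  # (S, T, I): pure gather
        mode = self.config.site_map_mode
        if mode == "identity":
            return hs, ("identity", hs)
        if mode == "scalar":
            y = self.params["site_a"] * hs + self.params["site_b"]
            return y, ("scalar", hs)
        if _kernels is not None:
            # (h * E_i) @ W1 == h * (E_i @ W1): precomputing EW collapses the
            # shared MLP to fused elementwise work
            EW = self.params["E"] @ self.params["mlp_W1"]
            S, T, I = hs.shape
            hs2 = np.ascontiguousarray(hs.reshape(S * T, I))
            y2, G = _kernels.site_mlp_forward(
                hs2, np.ascontiguousarray(EW), self.params["mlp_b1"],
                self.params["mlp_w2"], float(self.params["mlp_b2"][0]))
            return y2.reshape(S, T, I), ("embedding_fast", hs, hs2, G, EW)
        S_emb = hs[..., None] * self.params["E"]
        y, mlp_cache = self._mlp().forward(S_emb)
        return y, ("embedding", hs, S_emb, mlp_cache)

    def _site_backward(self, cache, dy: np.ndarray, grads: dict) -> np.ndarray:
        """Gradient of site outputs back to the gathered node activities."""
        mode = cache[0]
        if mode == "identity":
            return dy
        if mode == "scalar":
            hs = cache[1]
            grads["site_a"] += np.einsum("sti,sti->i", dy, hs)
            grads["site_b"] += dy.sum(axis=(0, 1))
            return dy * self.params["site_a"]
        if mode == "embedding_fast":
            _, hs, hs2, G, EW = cache
            S, T, I = hs.shape
            dy2 = np.ascontiguousarray(dy.reshape(S * T, I))
            dhs2, Q, db1, dw2, db2 = _kernels.site_mlp_backward(
                hs2, G, EW, self.params["mlp_w2"], dy2)
            grads["mlp_W1"] += self.params["E"].T @ Q
            grads["mlp_b1"] += db1
            grads["mlp_w2"] += dw2
            grads["mlp_b2"] += np.array([db2], dtype=grads["mlp_b2"].dtype)
            grads["E"] += Q @ self.params["mlp_W1"].T
            return dhs2.reshape(S, T, I)
        _, hs, S_emb, mlp_cache = cache
        mlp_grads, dS_emb = self._mlp().backward(mlp_cache, dy)
        for k, v in mlp_grads.items():
            grads[f"mlp_{k}"] += v
        grads["E"] += np.einsum("sti,stid->id", hs, dS_emb)
        return np.einsum("stid,id->sti", dS_emb, self.params["E"])

    def forward(self, x: np.ndarray, return_cache: bool = False):
        """Predicted site intensities at the model's anchors, (S, K, I)."""
        L = self.config.n_steps
        W = self.effective_weights()
        H, Z = rnn.simulate(W, self.params["b"], x, L, return_preact=True)
        anchors, acache = self.anchors()
        m = np.clip(anchors, 0.0, float(L - 1))
        lo = np.floor(m).astype(int)
        hi = np.minimum(lo + 1, L - 1)
        dm = m - lo
        steps = np.unique(np.concatenate([lo, hi]))
        pos = {s: i for i, s in enumerate(steps)}
        H_sel = H[:, steps, :]
        y_steps, site_cache = self._site_outputs(H_sel)
        pos_lo = np.array([pos[s] for s in lo])
        pos_hi = np.array([pos[s] for s in hi])
        preds = ((1.0 - dm)[None, :, None] * y_steps[:, pos_lo, :]
                 + dm[None, :, None] * y_steps[:, pos_hi, :])
        if not return_cache:
            return preds
        cache = {"x": x, "H": H, "Z": Z, "W": W, "anchors": anchors,
                 "acache": acache, "m": m, "pos_lo": pos_lo, "pos_hi": pos_hi,
                 "dm": dm, "steps": steps, "y_steps": y_steps,
                 "site_cache": site_cache}
        return preds, cache

    def predict(self, design: PerturbationDesign | None = None) -> np.ndarray:
        """Predictions for a perturbation design, with no measurements needed."""
        return self.forward(self.build_inputs(design))

    def predict_at_steps(self, design: PerturbationDesign | None,
                         steps: np.ndarray) -> np.ndarray:
        """Site intensities at explicit integer recurrent steps, (S, T, I)."""
        x = self.build_inputs(design)
        W = self.effective_weights()
        H = rnn.simulate(W, self.params["b"], x, self.config.n_steps)
        y, _ = self._site_outputs(H[:, np.asarray(steps, dtype=int), :])
        return y

    def site_step_trajectory(self, design: PerturbationDesign | None,
                             site_id: str) -> np.ndarray:
        """One site's predicted intensity at every recurrent step, (S, L)."""
        j = self.sites.site_ids.index(site_id)
        y = self.predict_at_steps(design, np.arange(self.config.n_steps))
        return y[:, :, j]

    # ------------------------------------------------------------------
    # backward
    # ------------------------------------------------------------------

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def backward(self, cache: dict, dpreds: np.ndarray,
                 design: PerturbationDesign | None = None,
                 grads: dict | None = None) -> dict[str, np.ndarray]:
        """Accumulate d(loss)/d(params) given d(loss)/d(predictions)."""
        design = design or self.design_space
        grads = grads if grads is not None else self.zero_grads()
        S, L, N = cache["H"].shape
        y_steps = cache["y_steps"]
        pos_lo, pos_hi, dm = cache["pos_lo"], cache["pos_hi"], cache["dm"]
        dy_steps = np.zeros_like(y_steps)
        K = dpreds.shape[1]
        for k in range(K):
            dy_steps[:, pos_lo[k], :] += (1.0 - dm[k]) * dpreds[:, k, :]
            dy_steps[:, pos_hi[k], :] += dm[k] * dpreds[:, k, :]
        if self.config.time_map_mode == "trainable":
            d_m = np.array([
                np.sum(dpreds[:, k, :] * (y_steps[:, pos_hi[k], :]
                                          - y_steps[:, pos_lo[k], :]))
                for k in range(K)])
            # clamping: anchors at/above L-1 carry no gradient
            d_m = np.where(cache["anchors"] >= L - 1, 0.0, d_m)
            ddelta, dalpha, du = time_map.anchors_backward(cache["acache"], d_m)
            u_raw = float(self.params["u_raw"][0])
            s = sigmoid(u_raw)
            grads["delta_raw"] += ddelta
            grads["alpha"] += np.array([dalpha])
            grads["u_raw"] += np.array([du * L * s * (1.0 - s)])
        dhs = self._site_backward(cache["site_cache"], dy_steps, grads)
        # scatter site gradients back to nodes
        dH_sel = dhs @ self.P.T.astype(dhs.dtype)
        dH = np.zeros((S, L, N), dtype=cache["H"].dtype)
        dH[:, cache["steps"], :] = dH_sel
        gW, gb, gx = rnn.backprop_through_time(cache["W"], cache["H"],
                                               cache["Z"], dH)
        grads["W"] += gW * self.mask
        grads["b"] += gb
        lig_col = {l: j for j, l in enumerate(design.ligands)}
        drug_col = {d: j for j, d in enumerate(design.drugs)}
        lsig = sigmoid(self.params["lig_raw"])
        dsig = sigmoid(self.params["drug_raw"])
        for p, (j_full, node) in enumerate(self.lig_pairs):
            lig = self.design_space.ligands[j_full]
            if lig in lig_col:
                grads["lig_raw"][p] += (
                    np.sum(gx[:, node] * design.ligand_matrix[:, lig_col[lig]])
                    * rnn.LIGAND_INPUT * lsig[p])
        for p, (j_full, node) in enumerate(self.drug_pairs):
            drug = self.design_space.drugs[j_full]
            if drug in drug_col:
                grads["drug_raw"][p] += (
                    np.sum(gx[:, node] * design.drug_matrix[:, drug_col[drug]])
                    * rnn.DRUG_INPUT * dsig[p])
        return grads

    # ------------------------------------------------------------------
    # checkpointing
    # ------------------------------------------------------------------

    def to_dict(self) -> dict:
        design, dt, lr = self.design_space.to_frames()
        return {
            "schema_version": CHECKPOINT_SCHEMA_VERSION,
            "config": self.config.to_dict(),
            "times": self.times.tolist(),
            "fixed_anchors": (self.fixed_anchors.tolist()
                              if self.fixed_anchors is not None else None),
            "network": {"node_ids": self.network.node_ids,
                        "edges": [list(e) for e in self.network.edges]},
            "sites": {"site_ids": self.sites.site_ids,
                      "site_to_node": self.sites.site_to_node},
            "design": {"design": design.to_dict(orient="list"),
                       "drug_targets": dt.to_dict(orient="list"),
                       "ligand_receptors": lr.to_dict(orient="list")},
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "PhosphoModel":
        import pandas as pd
        if d.get("schema_version") != CHECKPOINT_SCHEMA_VERSION:
            raise ValueError("unsupported checkpoint schema version")
        net = network_from_edges(
            list(d["network"]["node_ids"]),
            [(s, t, int(sg)) for s, t, sg in d["network"]["edges"]])
        sites = SiteAssignment(list(d["sites"]["site_ids"]),
                               dict(d["sites"]["site_to_node"]))
        design = PerturbationDesign.from_frames(
            pd.DataFrame(d["design"]["design"]),
            pd.DataFrame(d["design"]["drug_targets"]),
            pd.DataFrame(d["design"]["ligand_receptors"]))
        cfg = ModelConfig(**d["config"])
        fixed = (np.asarray(d["fixed_anchors"], dtype=float)
                 if d.get("fixed_anchors") is not None else None)
        model = cls(net, sites, design, np.asarray(d["times"], dtype=float),
                    cfg, fixed_anchors=fixed)
        for k, v in d["params"].items():
            model.params[k] = np.asarray(v, dtype=float)
        return model

    @classmethod
    def load(cls, path) -> "PhosphoModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def make_no_pkn_variant(model: PhosphoModel) -> PhosphoModel:
    """An otherwise identical model with a fully connected signaling layer.

    The adjacency mask is replaced by all-ones (so every node pair carries a
    trainable weight and no mode-of-action sign penalty applies).  Weights on
    the prior support are copied over, so the variant's family strictly
    contains the masked family.
    """
    cfg = ModelConfig(**{**model.config.to_dict(), "no_pkn": True})
    variant = PhosphoModel(model.network, model.sites, model.design_space,
                           model.times, cfg, fixed_anchors=model.fixed_anchors)
    for k, v in model.params.items():
        if k == "W":
            variant.params["W"] = model.effective_weights().copy()
        else:
            variant.params[k] = v.copy()
    return variant
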