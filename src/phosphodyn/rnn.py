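"""The recurrent signaling core.

Ligand and drug perturbations enter as constant per-node inputs; the state
vector is updated for a fixed number of discrete steps through the weighted,
mask-constrained interaction matrix:

    h_{t+1} = f(W h_t + b + x)

with a bounded activation f that is leaky-linear for negative pre-activations,
so a strong negative drug input (-5) pushes the target node's activity toward
zero smoothly and differentiably.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import check_finite

try:  # compiled inner loops; the NumPy paths below are the reference
    from . import _kernels
except ImportError:  # pragma: no cover
    _kernels = None

#: fixed magnitude of a drug perturbation before the trainable target weight
DRUG_INPUT = -5.0
#: fixed magnitude of a ligand stimulation before the trainable receptor weight
LIGAND_INPUT = 1.0

LEAK = 0.01  # slope of the negative branch


# ---------------------------------------------------------------------------
# activation
# ---------------------------------------------------------------------------

def activation(z: np.ndarray | float) -> np.ndarray:
    """Bounded, leaky activation used at every recurrent step.

    Piecewise: ``LEAK * z`` for z < 0 (leaky-linear), identity on [0, 0.5],
    and the saturating branch ``1 - 0.25/z`` above 0.5.  Continuous with
    continuous first derivative at both knots; bounded above by 1; f(0) = 0.
    """
    z = np.asarray(z, dtype=float)
    return np.where(z < 0, LEAK * z,
                    np.where(z <= 0.5, z, 1.0 - 0.25 / np.maximum(z, 0.5)))


def activation_grad(z: np.ndarray | float) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    return np.where(z < 0, LEAK,
                    np.where(z <= 0.5, 1.0, 0.25 / np.maximum(z, 0.5) ** 2))


# ---------------------------------------------------------------------------
# perturbation design
# ---------------------------------------------------------------------------

@dataclass
class PerturbationDesign:
    """Per-sample ligand/drug applications plus target annotations.

    ``ligand_matrix`` and ``drug_matrix`` are binary sample x ligand and
    sample x drug indicators; ``drug_targets`` / ``ligand_receptors`` map each
    perturbation name to the network nodes it acts on.
    """

    sample_ids: list[str]
    ligands: list[str]
    drugs: list[str]
    ligand_matrix: np.ndarray
    drug_matrix: np.ndarray
    drug_targets: dict[str, list[str]]
    ligand_receptors: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.ligand_matrix = np.asarray(self.ligand_matrix, dtype=float).reshape(
            len(self.sample_ids), len(self.ligands))
        self.drug_matrix = np.asarray(self.drug_matrix, dtype=float).reshape(
            len(self.sample_ids), len(self.drugs))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate_against(self, node_ids: list[str]) -> None:
        """Every applied ligand/drug must keep >=1 target in the network."""
        nodes = set(node_ids)
        for drug in self.drugs:
            targets = [t for t in self.drug_targets.get(drug, []) if t in nodes]
            if not targets:
                raise ValueError(
                    f"drug {drug!r} has no surviving target node in the network")
        for lig in self.ligands:
            recs = [r for r in self.ligand_receptors.get(lig, []) if r in nodes]
            if not recs:
                raise ValueError(
                    f"ligand {lig!r} has no surviving receptor node in the network")

    def subset(self, sample_ids: list[str]) -> "PerturbationDesign":
        rows = [self.sample_ids.index(s) for s in sample_ids]
        drugs = [d for j, d in enumerate(self.drugs)
                 if self.drug_matrix[rows, j].any()]
        dcols = [self.drugs.index(d) for d in drugs]
        return PerturbationDesign(
            sample_ids=list(sample_ids),
            ligands=list(self.ligands),
            drugs=drugs,
            ligand_matrix=self.ligand_matrix[rows],
            drug_matrix=self.drug_matrix[np.ix_(rows, dcols)] if dcols
            else np.zeros((len(rows), 0)),
            drug_targets={d: list(self.drug_targets[d]) for d in drugs},
            ligand_receptors={l: list(self.ligand_receptors[l])
                              for l in self.ligands},
        )

    # -- table I/O ----------------------------------------------------------

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        rows = []
        for i, s in enumerate(self.sample_ids):
            ligs = [l for j, l in enumerate(self.ligands) if self.ligand_matrix[i, j]]
            drgs = [d for j, d in enumerate(self.drugs) if self.drug_matrix[i, j]]
            rows.append({"sample": s, "ligand": ";".join(ligs), "drug": ";".join(drgs)})
        design = pd.DataFrame(rows)
        dt = pd.DataFrame([(d, t) for d in self.drugs for t in self.drug_targets[d]],
                          columns=["drug", "target"])
        lr = pd.DataFrame([(l, r) for l in self.ligands
                           for r in self.ligand_receptors[l]],
                          columns=["ligand", "receptor"])
        return design, dt, lr

    @classmethod
    def from_frames(cls, design: pd.DataFrame, drug_targets: pd.DataFrame,
                    ligand_receptors: pd.DataFrame) -> "PerturbationDesign":
        def split(cell) -> list[str]:
            if pd.isna(cell) or str(cell) == "":
                return []
            return str(cell).split(";")

        sample_ids = [str(s) for s in design["sample"]]
        lig_lists = [split(c) for c in design.get("ligand", [""] * len(design))]
        drug_lists = [split(c) for c in design.get("drug", [""] * len(design))]
        ligands = sorted({l for ls in lig_lists for l in ls})
        drugs = sorted({d for ds in drug_lists for d in ds})
        lmat = np.zeros((len(sample_ids), len(ligands)))
        dmat = np.zeros((len(sample_ids), len(drugs)))
        for i, (ls, ds) in enumerate(zip(lig_lists, drug_lists)):
            for l in ls:
                lmat[i, ligands.index(l)] = 1
            for d in ds:
                dmat[i, drugs.index(d)] = 1
        dt: dict[str, list[str]] = {d: [] for d in drugs}
        for _, row in drug_targets.iterrows():
            if str(row["drug"]) in dt:
                dt[str(row["drug"])].append(str(row["target"]))
        lr: dict[str, list[str]] = {l: [] for l in ligands}
        for _, row in ligand_receptors.iterrows():
            if str(row["ligand"]) in lr:
                lr[str(row["ligand"])].append(str(row["receptor"]))
        return cls(sample_ids, ligands, drugs, lmat, dmat, dt, lr)


@dataclass
class StateTrajectory:
    """Full sequence of recurrent states (samples x steps x nodes)."""

    values: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# inputs and simulation
# ---------------------------------------------------------------------------

def build_inputs(design: PerturbationDesign, node_ids: list[str],
                 ligand_weights: dict[tuple[str, str], float],
                 drug_weights: dict[tuple[str, str], float]) -> np.ndarray:
    """Constant per-sample per-node input vectors.

    input(node) = sum over applied ligands of (+1 * ligand_weight)
                + sum over applied drugs of (-5 * drug_weight).
    Weights are nonnegative scales per (perturbation, node) pair; signs are
    carried by the fixed input constants, never by the weights.
    """
    design.validate_against(node_ids)
    idx = {n: i for i, n in enumerate(node_ids)}
    x = np.zeros((design.n_samples, len(node_ids)))
    for j, lig in enumerate(design.ligands):
        applied = design.ligand_matrix[:, j]
        for rec in design.ligand_receptors[lig]:
            if rec in idx:
                w = ligand_weights.get((lig, rec), 1.0)
                if w < 0:
                    raise ValueError("ligand weights must be nonnegative")
                x[:, idx[rec]] += applied * LIGAND_INPUT * w
    for j, drug in enumerate(design.drugs):
        applied = design.drug_matrix[:, j]
        for tgt in design.drug_targets[drug]:
            if tgt in idx:
                w = drug_weights.get((drug, tgt), 1.0)
                if w < 0:
                    raise ValueError("drug weights must be nonnegative")
                x[:, idx[tgt]] += applied * DRUG_INPUT * w
    return x


def simulate(W: np.ndarray, b: np.ndarray, x: np.ndarray, n_steps: int,
             return_preact: bool = False):
    """Run the recurrent update for ``n_steps`` and return all states.

    ``h_0 = f(b + x)`` (the input-driven state before any propagation), then
    ``h_{t+1} = f(W h_t + b + x)``.  Returns an (S, L, N) array; with
    ``return_preact`` also the pre-activations needed for backpropagation.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    for name, arr in (("W", W), ("b", b), ("x", x)):
        check_finite(name, np.asarray(arr))
    x = np.atleast_2d(x)
    S, N = x.shape
    dtype = np.result_type(W, b, x)
    if _kernels is not None:
        bx = np.ascontiguousarray((b + x).astype(dtype, copy=False))
        H, Z = _kernels.simulate(np.ascontiguousarray(W.astype(dtype,
                                                              copy=False)),
                                 bx, n_steps)
    else:  # reference implementation
        H = np.empty((S, n_steps, N), dtype=dtype)
        Z = np.empty((S, n_steps, N), dtype=dtype)
        z = b + x
        Z[:, 0] = z
        H[:, 0] = activation(z)
        for t in range(1, n_steps):
            z = H[:, t - 1] @ W.T + b + x
            Z[:, t] = z
            H[:, t] = activation(z)
    if return_preact:
        return H, Z
    return H


def backprop_through_time(W: np.ndarray, H: np.ndarray, Z: np.ndarray,
                          dH: np.ndarray):
    """Reverse-mode pass through :func:`simulate`.

    Parameters
    ----------
    dH
        Gradient of the loss with respect to every state, (S, L, N).

    Returns
    -------
    (gW, gb, gx) : gradients w.r.t. the weight matrix, bias, and the constant
    per-sample input.
    """
    S, L, N = H.shape
    if _kernels is not None:
        return _kernels.backprop_through_time(
            np.ascontiguousarray(W), H, Z, np.ascontiguousarray(dH))
    gW = np.zeros_like(W)
    gb = np.zeros(N, dtype=W.dtype)
    gx = np.zeros((S, N), dtype=W.dtype)
    g = dH[:, L - 1].copy()
    for t in range(L - 1, -1, -1):
        dz = g * activation_grad(Z[:, t])
        gb += dz.sum(axis=0)
        gx += dz
        if t > 0:
            gW += dz.T @ H[:, t - 1]
            g = dH[:, t - 1] + dz @ W
    return gW, gb, gx
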