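"""End-to-end training of the composed model.

The objective is masked mean squared error on observed site intensities plus
L2 regularization of all parameters, a penalty for interaction weights whose
sign contradicts the curated mode of action, and a spectral-radius penalty
(estimated by a small number of power iterations) that keeps the recurrent
dynamics contractive.  Optimization is Adam under a cosine-annealing schedule
with warm restarts, with smooth (tanh) gradient clipping and additive Gaussian
gradient noise whose amplitude decays with the learning rate.  A mini-batch is
one sample's full time series, preserving temporal coherence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import rng_from_seed
from .io import PhosphoTimeCourse
from .model import PhosphoModel
from .pkn import spectral_radius_with_grad
from .rnn import PerturbationDesign

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    """Optimization hyperparameters.

    Defaults follow the recommended regime for the prior-constrained
    recurrent core: learning rate 2e-3, 5000 epochs, L2 weight 1e-5, and a
    spectral-radius estimate from 5 power iterations per update.  Protocol
    code overrides ``epochs`` (and sometimes ``batch_mode``) for small,
    CPU-friendly runs.
    """

    learning_rate: float = 2e-3
    epochs: int = 5000
    l2_lambda: float = 1e-5
    power_iterations: int = 5
    spectral_target: float = 0.95
    spectral_weight: float = 10.0
    sign_weight: float = 1.0
    grad_clip: float = 10.0
    grad_noise: float = 0.01
    batch_mode: str = "sample"  # sample | full | minibatch
    batch_size: int = 16  # group size in minibatch mode
    random_seed: int = 0
    restart_period: int | None = None  # default: epochs // 5
    lr_min_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for name in ("learning_rate", "l2_lambda", "spectral_weight",
                     "sign_weight", "grad_clip", "grad_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.batch_mode not in ("sample", "full", "minibatch"):
            raise ValueError("batch_mode must be 'sample', 'full' or 'minibatch'")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class LossReport:
    """Per-epoch loss components; they sum to the total."""

    total: np.ndarray
    mse: np.ndarray
    l2: np.ndarray
    sign: np.ndarray
    spectral: np.ndarray
    epochs: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.epochs is None:
            self.epochs = np.arange(1, self.total.size + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": self.epochs, "total": self.total,
                             "mse": self.mse, "l2": self.l2,
                             "sign": self.sign, "spectral": self.spectral})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# loss components
# ---------------------------------------------------------------------------

def masked_mse(pred: np.ndarray, obs: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared error over mask-true entries only."""
    mask = np.asarray(mask, dtype=bool)
    if pred.shape != obs.shape or pred.shape != mask.shape:
        raise ValueError("pred/obs/mask shapes must match")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no observed entries in the mask")
    diff = np.where(mask, pred - obs, 0.0)
    return float(np.sum(diff**2) / n)


def masked_mse_grad(pred: np.ndarray, obs: np.ndarray,
                    mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no observed entries in the mask")
    return np.where(mask, 2.0 * (pred - obs) / n, 0.0)


def sign_violation_penalty(W: np.ndarray, sign_matrix: np.ndarray,
                           return_grad: bool = False):
    """Sum over edges of relu(-sign * w)^2.

    Zero iff every trained weight agrees in sign with the curated mode of
    action (or is zero); the gradient pushes violating weights toward 0.
    """
    if W.shape != sign_matrix.shape:
        raise ValueError("W and sign_matrix shapes must match")
    viol = np.maximum(-sign_matrix * W, 0.0) * (sign_matrix != 0)
    pen = float(np.sum(viol**2))
    if not return_grad:
        return pen
    grad = -2.0 * viol * sign_matrix
    return pen, grad


def spectral_penalty(W: np.ndarray, target: float = 0.95,
                     power_iterations: int = 5, return_grad: bool = False):
    """(relu(rho_hat - target))^2 with rho_hat from power iteration."""
    rho, gW = spectral_radius_with_grad(W, power_iterations)
    excess = max(rho - target, 0.0)
    pen = float(excess**2)
    if not return_grad:
        return pen
    grad = 2.0 * excess * gW if excess > 0 else np.zeros_like(W)
    return pen, grad


def smooth_clip(flat_grad: np.ndarray, g_max: float) -> np.ndarray:
    """Rescale the gradient to norm g_max * tanh(|g| / g_max).

    Norm-preserving for small gradients, asymptotically bounded by ``g_max``.
    """
    norm = float(np.linalg.norm(flat_grad))
    if norm == 0.0 or g_max == 0.0:
        return flat_grad
    return flat_grad * (g_max * np.tanh(norm / g_max) / norm)


def cosine_warm_restart_lr(epoch: int, cfg: TrainingConfig) -> float:
    """Learning rate at a given 0-based epoch."""
    period = cfg.restart_period or max(cfg.epochs // 5, 1)
    t = epoch % period
    lr_min = cfg.learning_rate * cfg.lr_min_fraction
    return lr_min + 0.5 * (cfg.learning_rate - lr_min) * (
        1.0 + np.cos(np.pi * t / period))


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: dict[str, np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _flatten(grads: dict[str, np.ndarray]) -> np.ndarray:
    return np.concatenate([grads[k].ravel() for k in sorted(grads)])


def _unflatten(flat: np.ndarray, like: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    i = 0
    for k in sorted(like):
        n = like[k].size
        out[k] = flat[i:i + n].reshape(like[k].shape)
        i += n
    return out


def _batch_loss_and_grads(model: PhosphoModel, design: PerturbationDesign,
                          x: np.ndarray, obs: np.ndarray, mask: np.ndarray,
                          cfg: TrainingConfig):
    preds, cache = model.forward(x, return_cache=True)
    mse = masked_mse(preds, obs, mask)
    dpreds = masked_mse_grad(preds, obs, mask).astype(preds.dtype, copy=False)
    grads = model.backward(cache, dpreds, design)
    l2 = 0.0
    for k, v in model.params.items():
        l2 += float(np.sum(v**2))
        grads[k] += 2.0 * cfg.l2_lambda * v
    l2 *= cfg.l2_lambda
    W = model.effective_weights()
    if model.has_sign_prior and cfg.sign_weight > 0:
        sp, sg = sign_violation_penalty(W, model.sign_matrix, return_grad=True)
        sign_term = cfg.sign_weight * sp
        grads["W"] += cfg.sign_weight * sg * model.mask
    else:
        sign_term = 0.0
    if cfg.spectral_weight > 0:
        rp, rg = spectral_penalty(W, cfg.spectral_target,
                                  cfg.power_iterations, return_grad=True)
        spec_term = cfg.spectral_weight * rp
        grads["W"] += cfg.spectral_weight * rg * model.mask
    else:
        spec_term = 0.0
    components = {"mse": mse, "l2": l2, "sign": sign_term, "spectral": spec_term}
    components["total"] = mse + l2 + sign_term + spec_term
    return components, grads


def train(model: PhosphoModel, timecourse: PhosphoTimeCourse,
          design: PerturbationDesign, cfg: TrainingConfig | None = None,
          callback=None) -> LossReport:
    """Fit the model to an observed time course.

    ``timecourse`` samples/times/sites must align with the design and the
    model's site order.  Reproducible given ``cfg.random_seed``; aborts with a
    diagnostic naming the first non-finite loss component if training
    diverges.
    """
    cfg = cfg or TrainingConfig()
    if timecourse.site_ids != model.sites.site_ids:
        timecourse = timecourse.subset_sites(model.sites.site_ids)
    if list(timecourse.sample_ids) != list(design.sample_ids):
        raise ValueError("timecourse and design sample order must match")
    if timecourse.times.size != model.times.size or not np.allclose(
            timecourse.times, model.times):
        raise ValueError("timecourse times must match the model's times")
    rng = rng_from_seed(cfg.random_seed)
    opt = Adam(model.params)
    dtype = model.params["W"].dtype
    obs = timecourse.values.astype(dtype, copy=False)
    mask = timecourse.mask
    S = timecourse.n_samples
    history = {k: [] for k in ("total", "mse", "l2", "sign", "spectral")}
    for epoch in range(cfg.epochs):
        lr = cosine_warm_restart_lr(epoch, cfg)
        if cfg.batch_mode == "sample":
            order = rng.permutation(S)
            batches = [[int(i)] for i in order]
        elif cfg.batch_mode == "minibatch":
            order = rng.permutation(S)
            batches = [[int(i) for i in order[k:k + cfg.batch_size]]
                       for k in range(0, S, cfg.batch_size)]
        else:
            batches = [list(range(S))]
        epoch_comps = {k: 0.0 for k in history}
        # ligand/drug weights change every step, so inputs are rebuilt per batch
        for batch in batches:
            bdesign = design.subset([design.sample_ids[i] for i in batch])
            x = model.build_inputs(bdesign)
            comps, grads = _batch_loss_and_grads(
                model, bdesign, x, obs[batch], mask[batch], cfg)
            for k, v in comps.items():
                if not np.isfinite(v):
                    raise FloatingPointError(
                        f"non-finite loss component {k!r} at epoch {epoch + 1}")
            flat = _flatten(grads)
            if cfg.grad_clip > 0:
                flat = smooth_clip(flat, cfg.grad_clip)
            if cfg.grad_noise > 0:
                flat = (flat + rng.normal(0.0, cfg.grad_noise * lr,
                                          size=flat.size)).astype(dtype)
            grads = _unflatten(flat, model.params)
            opt.step(model.params, grads, lr)
            for k in epoch_comps:
                epoch_comps[k] += comps[k] / len(batches)
        for k in history:
            history[k].append(epoch_comps[k])
        if callback is not None:
            callback(epoch, epoch_comps)
    report = LossReport(**{k: np.asarray(v) for k, v in history.items()})
    q = max(cfg.epochs // 4, 1)
    if cfg.epochs >= 8 and np.mean(report.total[-q:]) > np.mean(report.total[:q]):
        logger.warning("training loss did not decrease overall")
    return report
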