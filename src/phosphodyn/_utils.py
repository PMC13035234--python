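"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np


def softplus(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable log(1 + exp(x))."""
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    # split to avoid overflow in exp for large |x|
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def inv_softplus(y: float) -> float:
    """Raw value r with softplus(r) = y (y > 0)."""
    if y <= 0:
        raise ValueError("softplus inverse requires y > 0")
    return float(np.log(np.expm1(y)))


def check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in {name}")


def rng_from_seed(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
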