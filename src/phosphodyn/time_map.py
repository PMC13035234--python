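"""Monotonic differentiable mapping from experimental times to recurrent steps.

Measured sampling times rarely coincide with the discrete update steps of the
recurrent core.  One trainable anchor per observed timepoint places that
timepoint at a fractional step position.  Anchors are parameterized to be
positive and strictly increasing — raw offsets pass through softplus and a
cumulative sum, are normalized to [0, 1], exponentially reweighted by a
trainable curvature alpha, and scaled by an upper bound u = L * sigmoid(u_raw)
— with the first anchor fixed to step 0.  Model outputs at fractional steps
are obtained by soft indexing: linear interpolation between the two bracketing
integer steps, which keeps the whole map differentiable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import sigmoid, softplus

logger = logging.getLogger(__name__)

_ALPHA_EPS = 1e-6


def compute_upper_bound(u_raw: float, n_steps: int) -> float:
    """u = L * sigmoid(u_raw), the largest step an anchor may reach."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    return float(n_steps * sigmoid(u_raw))


def _reweight(alpha: float, c: np.ndarray, variant: str):
    """g(alpha, c) mapping normalized cumulative offsets to [0, 1].

    Default (``shifted``): g = (e^{alpha c} - 1) / (e^{alpha} - 1), monotone in
    c with g(alpha, 0) = 0 and g(alpha, 1) = 1, and the analytic alpha -> 0
    limit g = c.  The ``literal`` variant g = (e^{alpha c} + 1)/(e^{alpha} + 1)
    reproduces the alternative parenthesization of the published formula; it
    does not pin g(0) = 0 and collapses to a constant at alpha = 0, so it is
    kept only behind this flag.
    """
    if variant == "literal":
        g = (np.exp(alpha * c) + 1.0) / (np.exp(alpha) + 1.0)
        dg_dc = alpha * np.exp(alpha * c) / (np.exp(alpha) + 1.0)
        return g, dg_dc
    if variant != "shifted":
        raise ValueError(f"unknown reweighting variant {variant!r}")
    if abs(alpha) < _ALPHA_EPS:
        # second-order series around alpha = 0
        g = c + 0.5 * alpha * c * (c - 1.0)
        dg_dc = 1.0 + 0.5 * alpha * (2.0 * c - 1.0)
        return g, dg_dc
    den = np.expm1(alpha)
    g = np.expm1(alpha * c) / den
    dg_dc = alpha * np.exp(alpha * c) / den
    return g, dg_dc


def _reweight_dalpha(alpha: float, c: np.ndarray, variant: str) -> np.ndarray:
    if variant == "literal":
        ea, eac = np.exp(alpha), np.exp(alpha * c)
        return (c * eac * (ea + 1.0) - (eac + 1.0) * ea) / (ea + 1.0) ** 2
    if abs(alpha) < _ALPHA_EPS:
        return 0.5 * c * (c - 1.0)
    den = np.expm1(alpha)
    eac = np.exp(alpha * c)
    return (c * eac * den - np.expm1(alpha * c) * np.exp(alpha)) / den**2


def compute_anchors(delta_raw: np.ndarray, alpha: float, u: float,
                    variant: str = "shifted",
                    return_cache: bool = False):
    """Fractional step positions for each timepoint.

    c = cumsum(softplus(delta_raw)); c_norm = (c - c_1)/(c_K - c_1);
    anchors = u * g(alpha, c_norm), with anchors[0] overridden to 0 (the first
    experimental time is pinned to the first recurrent step).
    """
    delta_raw = np.asarray(delta_raw, dtype=float)
    if delta_raw.ndim != 1 or delta_raw.size < 2:
        raise ValueError("need at least 2 timepoints")
    sp = softplus(delta_raw)
    c = np.cumsum(sp)
    den = c[-1] - c[0]
    if den <= 1e-12:
        raise ValueError("flat offsets: cumulative offsets are degenerate")
    cn = (c - c[0]) / den
    g, dg_dc = _reweight(alpha, cn, variant)
    anchors = u * g
    anchors[0] = 0.0
    if not np.all(np.diff(anchors) > 0):
        raise ValueError("anchors are not strictly increasing")
    if not return_cache:
        return anchors
    return anchors, {"sp": sp, "c": c, "den": den, "cn": cn, "g": g,
                     "dg_dc": dg_dc, "u": u, "alpha": alpha,
                     "variant": variant, "delta_raw": delta_raw}


def anchors_backward(cache: dict, danchors: np.ndarray):
    """Gradients of the anchors w.r.t. (delta_raw, alpha, u).

    The overridden first anchor carries no gradient.
    """
    danchors = np.asarray(danchors, dtype=float).copy()
    danchors[0] = 0.0
    g, dg_dc = cache["g"], cache["dg_dc"]
    u, alpha, cn, den = cache["u"], cache["alpha"], cache["cn"], cache["den"]
    du = float(np.sum(danchors * g))
    dg = danchors * u
    dalpha = float(np.sum(dg * _reweight_dalpha(alpha, cn, cache["variant"])))
    dcn = dg * dg_dc
    # cn_k = (c_k - c_0) / (c_{K-1} - c_0)
    dc = dcn / den
    dc[0] -= dcn.sum() / den
    corr = float(np.sum(dcn * cn)) / den
    dc[-1] -= corr
    dc[0] += corr
    # c = cumsum(sp) -> dsp_j = sum_{k >= j} dc_k
    dsp = np.cumsum(dc[::-1])[::-1]
    ddelta = dsp * sigmoid(cache["delta_raw"])
    return ddelta, dalpha, du


def one_to_one_anchors(times: np.ndarray, n_steps: int) -> np.ndarray:
    """Map the k-th experimental time directly to recurrent step k."""
    times = np.asarray(times)
    if times.size > n_steps:
        raise ValueError(f"{times.size} timepoints exceed {n_steps} steps")
    return np.arange(times.size, dtype=float)


def soft_index(values: np.ndarray, m: np.ndarray | float, axis: int = 1) -> np.ndarray:
    """Read ``values`` at fractional step positions by linear interpolation.

    y = (1 - dm) * values[floor(m)] + dm * values[ceil(m)] with dm = m - floor(m).
    Exact at integer m; piecewise linear and differentiable in between.
    Positions outside [0, L-1] are clamped (with a logged warning).
    """
    m = np.atleast_1d(np.asarray(m, dtype=float))
    L = values.shape[axis]
    if np.any(m < 0) or np.any(m > L - 1):
        logger.warning("fractional step(s) outside [0, %d] clamped", L - 1)
        m = np.clip(m, 0.0, float(L - 1))
    lo = np.floor(m).astype(int)
    hi = np.minimum(lo + 1, L - 1)
    dm = m - lo
    v_lo = np.take(values, lo, axis=axis)
    v_hi = np.take(values, hi, axis=axis)
    shape = [1] * values.ndim
    shape[axis] = m.size
    dm = dm.reshape(shape)
    return (1.0 - dm) * v_lo + dm * v_hi


def fit_anchors_from_reference_site(
    reference_values: np.ndarray,
    model_reference_trajectory: np.ndarray,
    n_steps: int,
    known_anchors: dict[int, float] | None = None,
    grid: float = 0.01,
) -> np.ndarray:
    """Estimate anchors from a densely sampled single reference phosphosite.

    For each timepoint, finds the fractional step (on a 0.01-step grid) where
    the trained model's reference-site trajectory best matches the measured
    value, scanning left to right so the result stays monotone.  A flat model
    trajectory admits no unique minimizer and raises an error.

    Parameters
    ----------
    reference_values
        Measured reference-site values, one per target time (in time order).
    model_reference_trajectory
        The model's reference-site output at every integer step, length L.
    known_anchors
        Optional {timepoint index: fractional step} constraints (e.g. anchors
        already learned for trained timepoints); estimated anchors are kept
        monotone with respect to these.
    """
    traj = np.asarray(model_reference_trajectory, dtype=float)
    if traj.ndim != 1 or traj.size != n_steps:
        raise ValueError("model reference trajectory must have one value per step")
    if float(np.ptp(traj)) < 1e-8:
        raise ValueError("flat reference trajectory: timing cannot be recovered")
    ref = np.asarray(reference_values, dtype=float)
    K = ref.size
    mgrid = np.arange(0.0, n_steps - 1 + 0.5 * grid, grid)
    ygrid = soft_index(traj[None, :], mgrid, axis=1)[0]
    known = dict(known_anchors or {})
    anchors = np.empty(K)
    lower = 0.0
    for k in range(K):
        if k in known:
            anchors[k] = known[k]
            lower = known[k]
            continue
        # next hard constraint to the right bounds the search window
        upper = float(n_steps - 1)
        for kk in sorted(known):
            if kk > k:
                upper = known[kk]
                break
        sel = (mgrid >= lower) & (mgrid <= upper)
        if not sel.any():
            sel = np.isclose(mgrid, lower)
        err = (ygrid[sel] - ref[k]) ** 2
        anchors[k] = mgrid[sel][int(np.argmin(err))]
        lower = anchors[k]
    anchors[0] = known.get(0, 0.0)
    return anchors


@dataclass
class TimeAnchors:
    """Trainable time-map parameters and their derived anchors."""

    delta_raw: np.ndarray
    u_raw: float
    alpha: float
    n_steps: int
    variant: str = "shifted"

    def anchors(self) -> np.ndarray:
        u = compute_upper_bound(self.u_raw, self.n_steps)
        return compute_anchors(self.delta_raw, self.alpha, u, self.variant)

    def to_frame(self, times: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({"time_minutes": np.asarray(times, dtype=float),
                             "fractional_step": self.anchors()})


def export_anchors(times: np.ndarray, anchors: np.ndarray, path) -> None:
    pd.DataFrame({"time_minutes": np.asarray(times, dtype=float),
                  "fractional_step": np.asarray(anchors, dtype=float)}
                 ).to_csv(path, sep="\t", index=False)
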