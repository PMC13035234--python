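"""Compiled inner loops for the recurrent core and the site map.

The recurrent update and its backward pass are step-by-step loops, and the
site map applies one shared MLP to every (sample, step, site) scalar; both are
implemented here as numba kernels.  The site map exploits the factorization
``(h_site * E_i) @ W1 = h_site * (E_i @ W1)``: with ``EW = E @ W1``
precomputed, the whole layer is elementwise over (batch, site, hidden) and
never materializes the scaled-embedding tensor.

All kernels are exact (no fastmath), so results match the plain NumPy
reference implementations bit for bit; tests pin the gradients against finite
differences through these paths.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LEAK = 0.01


@njit(cache=False)
def _act(z):
    if z < 0.0:
        return LEAK * z
    if z <= 0.5:
        return z
    return 1.0 - 0.25 / z


@njit(cache=False)
def _act_grad(z):
    if z < 0.0:
        return LEAK
    if z <= 0.5:
        return 1.0
    return 0.25 / (z * z)


@njit(cache=False)
def simulate(W, bx, n_steps):
    """Forward recurrence; returns states H and pre-activations Z, (S, L, N)."""
    S, N = bx.shape
    H = np.empty((S, n_steps, N), dtype=W.dtype)
    Z = np.empty((S, n_steps, N), dtype=W.dtype)
    WT = np.ascontiguousarray(W.T)
    for s in range(S):
        for n in range(N):
            z = bx[s, n]
            Z[s, 0, n] = z
            H[s, 0, n] = _act(z)
    for t in range(1, n_steps):
        zt = np.dot(np.ascontiguousarray(H[:, t - 1]), WT)
        for s in range(S):
            for n in range(N):
                z = zt[s, n] + bx[s, n]
                Z[s, t, n] = z
                H[s, t, n] = _act(z)
    return H, Z


@njit(cache=False)
def backprop_through_time(W, H, Z, dH):
    """Reverse pass of :func:`simulate`; returns (gW, gb, gx)."""
    S, L, N = H.shape
    gW = np.zeros_like(W)
    gb = np.zeros(N, dtype=W.dtype)
    gx = np.zeros((S, N), dtype=W.dtype)
    g = dH[:, L - 1].copy()
    dz = np.empty((S, N), dtype=W.dtype)
    for t in range(L - 1, -1, -1):
        for s in range(S):
            for n in range(N):
                dz[s, n] = g[s, n] * _act_grad(Z[s, t, n])
                gb[n] += dz[s, n]
                gx[s, n] += dz[s, n]
        if t > 0:
            gW += np.dot(dz.T, np.ascontiguousarray(H[:, t - 1]))
            g = dH[:, t - 1] + np.dot(dz, W)
    return gW, gb, gx


@njit(cache=False)
def site_mlp_forward(hs, EW, b1, w2, b2):
    """Shared-MLP site intensities from gathered node activities.

    hs: (B, I) node activity per flattened (sample, step) row and site;
    EW = E @ W1: (I, Hh).  Returns the per-site outputs and the hidden
    activations needed for the backward pass.
    """
    B, I = hs.shape
    Hh = EW.shape[1]
    y = np.empty((B, I), dtype=hs.dtype)
    G = np.empty((B, I, Hh), dtype=hs.dtype)
    for b in range(B):
        for i in range(I):
            acc = b2
            h = hs[b, i]
            for k in range(Hh):
                g = np.tanh(h * EW[i, k] + b1[k])
                G[b, i, k] = g
                acc += g * w2[k]
            y[b, i] = acc
    return y, G


@njit(cache=False)
def site_mlp_backward(hs, G, EW, w2, dy):
    """Reverse pass of :func:`site_mlp_forward`.

    Returns (dhs, Q, db1, dw2, db2) where Q[i, k] = sum_b hs * dA1 collapses
    the batch so that dW1 = E.T @ Q and dE = Q @ W1.T outside the kernel.
    """
    B, I = hs.shape
    Hh = EW.shape[1]
    dhs = np.zeros((B, I), dtype=hs.dtype)
    Q = np.zeros((I, Hh), dtype=hs.dtype)
    db1 = np.zeros(Hh, dtype=hs.dtype)
    dw2 = np.zeros(Hh, dtype=hs.dtype)
    db2 = 0.0
    for b in range(B):
        for i in range(I):
            d = dy[b, i]
            if d == 0.0:
                continue
            db2 += d
            h = hs[b, i]
            for k in range(Hh):
                g = G[b, i, k]
                dw2[k] += g * d
                da = d * w2[k] * (1.0 - g * g)
                db1[k] += da
                Q[i, k] += h * da
                dhs[b, i] += da * EW[i, k]
    return dhs, Q, db1, dw2, db2
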