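"""Compiled kernels for MLP training: cross-entropy loss/gradient and rprop+.

The weight vector layout for a network with n inputs and m hidden neurons is

    m == 0 : [w_0, w_1, ..., w_n]                         (n+1 weights)
    m >= 1 : [W_00..W_0m-1, W_10.., ..., W_n0..,          ((n+1)*m hidden,
              w_0, w_1, ..., w_m]                          then m+1 output)

where the hidden block is the (n+1, m) matrix W_ij (row i = input neuron,
i = 0 the constant neuron) flattened in C order, and w_0 is the output
intercept.  The design matrix X1 carries the constant neuron as column 0.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# clip bound applied to predicted probabilities inside the error only; the
# gradient uses the exact (unclipped) residual mu - y.
_SIGMOID_CUT = 700.0  # |z| beyond which exp overflows float64


@njit(cache=True)
def _sigmoid(z):
    if z >= 0.0:
        if z > _SIGMOID_CUT:
            return 1.0
        return 1.0 / (1.0 + math.exp(-z))
    if z < -_SIGMOID_CUT:
        return 0.0
    e = math.exp(z)
    return e / (1.0 + e)


@njit(cache=True)
def loss_and_grad(X1, y, w, m, clip_eps, grad):
    """Summed cross-entropy and its exact gradient; returns the error."""
    N, p1 = X1.shape
    P = w.size
    for p in range(P):
        grad[p] = 0.0
    E = 0.0
    if m == 0:
        for i in range(N):
            z = 0.0
            for k in range(p1):
                z += X1[i, k] * w[k]
            mu = _sigmoid(z)
            muc = min(max(mu, clip_eps), 1.0 - clip_eps)
            E -= y[i] * math.log(muc) + (1.0 - y[i]) * math.log(1.0 - muc)
            d = mu - y[i]
            for k in range(p1):
                grad[k] += d * X1[i, k]
        return E
    h = np.empty(m)
    off = p1 * m  # start of the output block
    for i in range(N):
        for j in range(m):
            zj = 0.0
            for k in range(p1):
                zj += X1[i, k] * w[k * m + j]
            h[j] = _sigmoid(zj)
        z = w[off]
        for j in range(m):
            z += w[off + 1 + j] * h[j]
        mu = _sigmoid(z)
        muc = min(max(mu, clip_eps), 1.0 - clip_eps)
        E -= y[i] * math.log(muc) + (1.0 - y[i]) * math.log(1.0 - muc)
        d = mu - y[i]
        grad[off] += d
        for j in range(m):
            grad[off + 1 + j] += d * h[j]
            dh = d * w[off + 1 + j] * h[j] * (1.0 - h[j])
            for k in range(p1):
                grad[k * m + j] += dh * X1[i, k]
    return E


@njit(cache=True)
def rprop_train(X1, y, w, m, eta_plus, eta_minus, delta_zero, delta_max, delta_min,
                threshold, stepmax, clip_eps):
    """Full-batch rprop+ with weight backtracking.

    Per weight: same gradient sign grows the step by eta_plus (capped at
    delta_max); a sign flip shrinks it by eta_minus (floored at delta_min),
    reverts that weight's last update and zeroes its stored gradient.  Stops
    when the gradient max-norm falls to `threshold` (converged) or after
    `stepmax` iterations.

    Returns (error, n_iter, converged, diverged); w is updated in place.
    """
    P = w.size
    grad = np.zeros(P)
    grad_prev = np.zeros(P)
    dw_prev = np.zeros(P)
    delta = np.full(P, delta_zero)
    E = loss_and_grad(X1, y, w, m, clip_eps, grad)
    if not np.isfinite(E):
        return E, 0, False, True
    it = 0
    converged = False
    while it < stepmax:
        gmax = 0.0
        for p in range(P):
            a = abs(grad[p])
            if a > gmax:
                gmax = a
        if gmax <= threshold:
            converged = True
            break
        for p in range(P):
            s = grad[p] * grad_prev[p]
            if s > 0.0:
                d = delta[p] * eta_plus
                if d > delta_max:
                    d = delta_max
                delta[p] = d
                step = -d if grad[p] > 0.0 else d
                w[p] += step
                dw_prev[p] = step
                grad_prev[p] = grad[p]
            elif s < 0.0:
                d = delta[p] * eta_minus
                if d < delta_min:
                    d = delta_min
                delta[p] = d
                w[p] -= dw_prev[p]
                dw_prev[p] = 0.0
                grad_prev[p] = 0.0
            else:
                if grad[p] > 0.0:
                    step = -delta[p]
                elif grad[p] < 0.0:
                    step = delta[p]
                else:
                    step = 0.0
                w[p] += step
                dw_prev[p] = step
                grad_prev[p] = grad[p]
        it += 1
        E = loss_and_grad(X1, y, w, m, clip_eps, grad)
        if not np.isfinite(E):
            return E, it, False, True
    return E, it, converged, False
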