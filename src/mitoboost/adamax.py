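"""Adamax: the infinity-norm variant of the Adam gradient optimizer.

State per step t (all element-wise):

    m_t = beta1 * m_{t-1} + (1 - beta1) * G_t          (first moment)
    u_t = max(beta2 * u_{t-1}, |G_t|)                  (infinity-norm moment)
    w_t = w_{t-1} - eta / (1 - beta1^t) * m_t / (u_t + eps)

Only the first moment is bias-corrected; the infinity-norm moment needs no
correction.  eps guards the u_t = 0 corner (all-zero gradients so far).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class AdamaxState:
    w: np.ndarray
    m: np.ndarray
    u: np.ndarray
    t: int = 0
    eta: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta1 < 1.0 and 0.0 <= self.beta2 < 1.0):
            raise ValueError("beta1, beta2 must lie in [0, 1)")
        if self.t < 0:
            raise ValueError("step counter must be non-negative")


def init_state(w0, eta: float = 0.01, beta1: float = 0.9, beta2: float = 0.999,
               eps: float = 1e-8) -> AdamaxState:
    w0 = np.atleast_1d(np.asarray(w0, dtype=float)).copy()
    return AdamaxState(w=w0, m=np.zeros_like(w0), u=np.zeros_like(w0),
                       eta=eta, beta1=beta1, beta2=beta2, eps=eps)


def adamax_step(state: AdamaxState, grad) -> AdamaxState:
    """One update; returns a new state, the input state is untouched."""
    grad = np.asarray(grad, dtype=float)
    if grad.shape != state.w.shape:
        raise ValueError("gradient shape does not match weights")
    if not np.all(np.isfinite(grad)):
        raise ValueError("non-finite gradient")
    t = state.t + 1
    m = state.beta1 * state.m + (1.0 - state.beta1) * grad
    u = np.maximum(state.beta2 * state.u, np.abs(grad))
    corr = 1.0 - state.beta1 ** t
    w = state.w - (state.eta / corr) * m / (u + state.eps)
    return replace(state, w=w, m=m, u=u, t=t)


def minimize(objective, gradient, w0, steps: int, eta: float = 0.01,
             beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
    """Apply adamax_step ``steps`` times; returns (w_final, loss trace).

    The trace records the objective *before* each step (length ``steps``).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    state = init_state(w0, eta=eta, beta1=beta1, beta2=beta2, eps=eps)
    losses = np.empty(steps)
    for k in range(steps):
        losses[k] = float(objective(state.w))
        state = adamax_step(state, gradient(state.w))
    return state.w, losses
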