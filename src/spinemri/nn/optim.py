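"""First-principles optimizers: plain SGD and Adam.

Parameters live in a "tree" — a list (one entry per layer) of dicts mapping
names to ndarrays — and both optimizers are purely functional: they return
new trees and never mutate their inputs.  Bare ndarrays and flat dicts are
accepted too, which keeps the single-tensor unit semantics easy to test.

The Adam second moment uses the exponentially weighted recursion

    v_t = beta2 * v_{t-1} + (1 - beta2) * g_t^2,

whose closed form is ``v_t = (1 - beta2) * sum_i beta2^(t-i) g_i^2``; the
bias correction ``v_t / (1 - beta2^t)`` makes the estimate exact for a
static squared gradient (v-hat = g^2 for constant g, at every t).  The first
moment is handled the same way with beta1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

import numpy as np

Tree = Any  # ndarray | dict[str, Tree] | list[Tree]


def tree_map(fn, *trees: Tree) -> Tree:
    """Apply *fn* leafwise over parallel trees of ndarrays/scalars."""
    head = trees[0]
    if isinstance(head, dict):
        return {k: tree_map(fn, *(t[k] for t in trees)) for k in head}
    if isinstance(head, (list, tuple)):
        return type(head)(tree_map(fn, *parts) for parts in zip(*trees))
    return fn(*trees)


def _check_shapes(params: Tree, grads: Tree) -> None:
    def chk(p, g):
        p, g = np.asarray(p), np.asarray(g)
        if p.shape != g.shape:
            raise ValueError(f"shape mismatch: param {p.shape} vs grad {g.shape}")
        return None

    tree_map(chk, params, grads)


def sgd_step(params: Tree, grads: Tree, learning_rate: float) -> Tree:
    """One plain gradient-descent update: ``p' = p - eta * g``.

    Applied uniformly to every weight and bias in the tree.
    """
    if learning_rate <= 0:
        raise ValueError("learning_rate must be > 0")
    _check_shapes(params, grads)
    return tree_map(lambda p, g: p - learning_rate * g, params, grads)


@dataclass
class AdamState:
    """Adam hyperparameters and accumulated moments.

    ``m`` / ``v`` hold the first and second moment trees (initialized lazily
    to zeros on the first step); ``t`` counts completed steps.
    """

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: Tree | None = None
    v: Tree | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta1 < 1.0:
            raise ValueError("beta1 must lie in [0, 1)")
        if not 0.0 <= self.beta2 < 1.0:
            raise ValueError("beta2 must lie in [0, 1)")
        if self.t < 0:
            raise ValueError("t must be >= 0")


def adam_step(state: AdamState, params: Tree, grads: Tree) -> tuple[AdamState, Tree]:
    """One Adam update; returns ``(new_state, new_params)``.

    The update is ``p' = p - eta * m_hat / (sqrt(v_hat) + eps)`` with
    bias-corrected moments ``m_hat = m_t / (1 - beta1^t)`` and
    ``v_hat = v_t / (1 - beta2^t)``.
    """
    _check_shapes(params, grads)
    m = state.m if state.m is not None else tree_map(np.zeros_like, grads)
    v = state.v if state.v is not None else tree_map(np.zeros_like, grads)
    t = state.t + 1
    b1, b2 = state.beta1, state.beta2
    m = tree_map(lambda m_, g: b1 * m_ + (1 - b1) * g, m, grads)
    v = tree_map(lambda v_, g: b2 * v_ + (1 - b2) * g * g, v, grads)
    c1 = 1.0 - b1**t
    c2 = 1.0 - b2**t
    lr, eps = state.learning_rate, state.eps
    new_params = tree_map(
        lambda p, m_, v_: p - lr * (m_ / c1) / (np.sqrt(v_ / c2) + eps),
        params,
        m,
        v,
    )
    return replace(state, t=t, m=m, v=v), new_params


def second_moment_explicit(grads_history: list[np.ndarray], beta2: float) -> np.ndarray:
    """Brute-force second moment ``(1-b2) * sum_i b2^(t-i) g_i^2``.

    Independent oracle for the recursive update in :func:`adam_step`; kept
    deliberately as a direct summation over the stored gradient history.
    """
    t = len(grads_history)
    v = np.zeros_like(np.asarray(grads_history[0], dtype=float))
    for i, g in enumerate(grads_history, start=1):
        v = v + beta2 ** (t - i) * np.asarray(g, dtype=float) ** 2
    return (1.0 - beta2) * v
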