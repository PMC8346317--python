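"""Low-level layer operations: 3x3 convolution, batch normalization, ReLU.

Everything here is plain numpy with hand-derived gradients.  Convolutions
use stride 1 and zero padding 1, so spatial dimensions are preserved — a
requirement of the elementwise skip connection in the residual denoiser.
Forward functions return the caches their matching backward functions need.

Activations use NHWC layout, ``(batch, height, width, channels)``, which
keeps the channel contraction contiguous so each of the nine kernel offsets
is a single BLAS matmul.  Convolution weights are stored as
``(3, 3, in_channels, out_channels)``, matching the conventional
"3 x 3 x C_in x C_out" description of layer sizes.
"""

from __future__ import annotations

import numpy as np

KERNEL = 3
PAD = 1


def conv_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """Same-size 3x3 convolution by shift-and-matmul over the 9 offsets.

    Parameters
    ----------
    x : (B, H, W, C_in)
    weight : (3, 3, C_in, C_out)
    bias : (C_out,)
    """
    b, h, w, c_in = x.shape
    if weight.shape[:3] != (KERNEL, KERNEL, c_in):
        raise ValueError(
            f"weight shape {weight.shape} incompatible with input channels {c_in}"
        )
    c_out = weight.shape[3]
    xp = np.pad(x, ((0, 0), (PAD, PAD), (PAD, PAD), (0, 0)))
    y = np.broadcast_to(bias, (b, h, w, c_out)).copy()
    for i in range(KERNEL):
        for j in range(KERNEL):
            y += xp[:, i : i + h, j : j + w, :] @ weight[i, j]
    return y, (xp, weight)


def conv_backward(dy: np.ndarray, cache):
    """Gradients of the same-size convolution w.r.t. input, weight, bias."""
    xp, weight = cache
    b, h, w, c_out = dy.shape
    c_in = weight.shape[2]
    dweight = np.empty_like(weight)
    dxp = np.zeros_like(xp)
    dyf = dy.reshape(-1, c_out)
    for i in range(KERNEL):
        for j in range(KERNEL):
            xs = xp[:, i : i + h, j : j + w, :]
            dweight[i, j] = xs.reshape(-1, c_in).T @ dyf
            dxp[:, i : i + h, j : j + w, :] += dy @ weight[i, j].T
    dbias = dyf.sum(axis=0)
    dx = dxp[:, PAD : PAD + h, PAD : PAD + w, :]
    return dx, dweight, dbias


def relu_forward(x: np.ndarray):
    y = np.maximum(x, 0)
    return y, (x > 0)


def relu_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dy * mask


def batch_norm(
    x: np.ndarray,
    gamma,
    beta,
    eps: float = 1e-5,
    mode: str = "train",
    running_mean=None,
    running_var=None,
):
    """Standalone batch normalization over axis 0.

    *x* may be 1-D (one channel, shape ``(N,)``) or 2-D (``(N, C)``).  In
    training mode the batch is standardized by its own mean and (biased)
    variance, then affinely transformed: ``y = gamma * xhat + beta``; a batch
    of size 1 is rejected since its variance carries no information.  In
    inference mode the provided running statistics are used instead.

    A zero-variance batch maps to ``beta`` exactly (the eps guard sends
    ``xhat`` to 0).
    """
    x = np.asarray(x, dtype=float)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if mode == "train":
        if x.shape[0] < 2:
            raise ValueError("batch normalization in training mode needs batch size >= 2")
        mean = x.mean(axis=0)
        var = x.var(axis=0)
    elif mode == "inference":
        if running_mean is None or running_var is None:
            raise ValueError("inference mode requires running_mean and running_var")
        mean, var = np.asarray(running_mean, float), np.asarray(running_var, float)
        if np.any(var < 0):
            raise ValueError("running variance must be nonnegative")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    # a numerically-degenerate batch (variance at rounding level) maps to
    # beta exactly rather than amplifying float noise through 1/sqrt(eps)
    zero_var = var <= np.finfo(float).eps * (mean**2 + 1.0)
    xhat = np.where(zero_var, 0.0, (x - mean) / np.sqrt(var + eps))
    return np.asarray(gamma) * xhat + np.asarray(beta)


def bn_forward(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = 1e-5):
    """Per-channel batch norm over (B, H, W) for NHWC activations, train mode."""
    mean = x.mean(axis=(0, 1, 2))
    var = x.var(axis=(0, 1, 2))
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean) * inv_std
    y = gamma * xhat + beta
    return y, (xhat, inv_std, gamma), (mean, var)


def bn_backward(dy: np.ndarray, cache):
    """Gradient of train-mode batch norm (mean/var both differentiated)."""
    xhat, inv_std, gamma = cache
    axes = (0, 1, 2)
    m = dy.shape[0] * dy.shape[1] * dy.shape[2]
    dgamma = (dy * xhat).sum(axis=axes)
    dbeta = dy.sum(axis=axes)
    dx = (gamma * inv_std) * (dy - dbeta / m - xhat * (dgamma / m))
    return dx, dgamma, dbeta


def bn_inference(x, gamma, beta, running_mean, running_var, eps: float = 1e-5):
    """Inference-mode batch norm using stored running statistics."""
    inv_std = 1.0 / np.sqrt(running_var + eps)
    return gamma * (x - running_mean) * inv_std + beta
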