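"""The residual denoising network.

A stack of same-size 3x3 convolutions learns the *noise map* of a corrupted
magnitude image: if ``H(x)`` is the clean-image mapping one would like, the
network fits the residual ``F(x) = H(x) - x`` instead, and the denoised
estimate is recovered through the identity skip connection
``denoised = noisy - F_hat(noisy)`` (with ``F_hat`` predicting the noise, the
sign convention used throughout this package).  Residual fitting is the
standard cure for vanishing gradients in deep denoisers and is what makes
depth-15 training stable.

Architecture (default depth 15):

* layer 1   — conv 3x3x1x64 + ReLU                     (input layer)
* layers 2..14 — conv 3x3x64x64 + batch norm + ReLU    (13 hidden layers)
* layer 15  — conv 3x3x64x1, linear                    (output layer)

Reduced depths (3, 7, ...) keep the same input/output layers and shrink the
hidden stack; they are first-class so that CPU-scale experiments and tests
stay fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ..phantoms import MIN_IMAGE_SIZE, validate_image
from . import layers as L


@dataclass(frozen=True)
class LayerSpec:
    """Shape and feature flags of one convolutional layer."""

    kind: str  # input_conv | hidden_conv | output_conv
    in_channels: int
    out_channels: int
    has_bn: bool
    has_activation: bool
    kernel: int = 3

    def n_parameters(self) -> int:
        n = self.kernel * self.kernel * self.in_channels * self.out_channels
        n += self.out_channels  # conv bias (retained even under BN)
        if self.has_bn:
            n += 2 * self.out_channels  # gamma, beta
        return n


@dataclass(frozen=True)
class DenoiserSpec:
    """Full architecture: depth, channel width, and the derived layer list."""

    depth: int = 15
    channels: int = 64
    residual: bool = True

    def __post_init__(self) -> None:
        if self.depth < 3:
            raise ValueError("depth must be >= 3 (input, >=1 hidden, output)")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")

    @property
    def hidden_layers(self) -> int:
        return self.depth - 2

    @property
    def layers(self) -> list[LayerSpec]:
        specs = [LayerSpec("input_conv", 1, self.channels, False, True)]
        specs += [
            LayerSpec("hidden_conv", self.channels, self.channels, True, True)
            for _ in range(self.hidden_layers)
        ]
        specs.append(LayerSpec("output_conv", self.channels, 1, False, False))
        return specs

    def n_parameters(self) -> int:
        """Total trainable parameter count (enumerated per layer)."""
        return sum(s.n_parameters() for s in self.layers)


class ResidualDenoiser:
    """A built network: parameter tensors plus forward/backward machinery.

    Use :func:`build_model` (or ``ResidualDenoiser(spec, init_seed)``) to
    construct; :meth:`denoise` for inference; the training loop lives in
    :mod:`spinemri.nn.training`.
    """

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(self, spec: DenoiserSpec, init_seed: int = 0, dtype=np.float64):
        self.spec = spec
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(init_seed)
        self.params: list[dict[str, np.ndarray]] = []
        self.running: list[dict[str, np.ndarray] | None] = []
        prev = None
        for ls in spec.layers:
            if prev is not None and ls.in_channels != prev:
                raise ValueError(
                    f"channel chaining broken: layer expects {ls.in_channels}, "
                    f"previous produced {prev}"
                )
            prev = ls.out_channels
            fan_in = ls.kernel * ls.kernel * ls.in_channels
            std = np.sqrt(2.0 / fan_in)  # He init for rectifier stacks
            p = {
                "weight": rng.normal(0.0, std, (ls.kernel, ls.kernel, ls.in_channels, ls.out_channels)).astype(self.dtype),
                "bias": np.zeros(ls.out_channels, dtype=self.dtype),
            }
            if ls.has_bn:
                p["gamma"] = np.ones(ls.out_channels, dtype=self.dtype)
                p["beta"] = np.zeros(ls.out_channels, dtype=self.dtype)
                self.running.append(
                    {
                        "mean": np.zeros(ls.out_channels, dtype=self.dtype),
                        "var": np.ones(ls.out_channels, dtype=self.dtype),
                    }
                )
            else:
                self.running.append(None)
            self.params.append(p)

    # -- introspection ----------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(v.size for p in self.params for v in p.values()))

    # -- forward ----------------------------------------------------------

    def forward_batch(self, x: np.ndarray, train: bool = False):
        """Run a (B, H, W, 1) batch through the network.

        Returns the residual (noise-map) prediction; in training mode also
        returns the caches needed by :meth:`backward_batch` and updates the
        BN running statistics.
        """
        caches = []
        out = x.astype(self.dtype, copy=False)
        for ls, p, run in zip(self.spec.layers, self.params, self.running):
            out, conv_cache = L.conv_forward(out, p["weight"], p["bias"])
            bn_cache = None
            if ls.has_bn:
                if train:
                    out, bn_cache, (bmean, bvar) = L.bn_forward(
                        out, p["gamma"], p["beta"], self.BN_EPS
                    )
                    m = self.BN_MOMENTUM
                    run["mean"] = (1 - m) * run["mean"] + m * bmean
                    run["var"] = (1 - m) * run["var"] + m * bvar
                else:
                    out = L.bn_inference(
                        out, p["gamma"], p["beta"], run["mean"], run["var"], self.BN_EPS
                    )
            act_mask = None
            if ls.has_activation:
                out, act_mask = L.relu_forward(out)
            caches.append((conv_cache, bn_cache, act_mask))
        if train:
            return out, caches
        return out

    def backward_batch(self, dresidual: np.ndarray, caches):
        """Backpropagate a gradient w.r.t. the residual output.

        Returns a gradient tree shaped like ``self.params``.
        """
        grads = [dict() for _ in self.params]
        dy = dresidual.astype(self.dtype, copy=False)
        for idx in range(len(self.params) - 1, -1, -1):
            ls = self.spec.layers[idx]
            conv_cache, bn_cache, act_mask = caches[idx]
            if ls.has_activation:
                dy = L.relu_backward(dy, act_mask)
            if ls.has_bn:
                dy, dgamma, dbeta = L.bn_backward(dy, bn_cache)
                grads[idx]["gamma"] = dgamma
                grads[idx]["beta"] = dbeta
            dy, dweight, dbias = L.conv_backward(dy, conv_cache)
            grads[idx]["weight"] = dweight
            grads[idx]["bias"] = dbias
        return grads

    # -- user-facing inference -------------------------------------------

    def forward(self, noisy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Denoise one 2-D image.

        Returns ``(residual_estimate, denoised)`` with
        ``denoised = noisy - residual_estimate`` holding elementwise by
        construction of the skip connection.
        """
        img = validate_image(noisy)
        if min(img.shape) < MIN_IMAGE_SIZE:
            raise ValueError(f"image smaller than the {MIN_IMAGE_SIZE}px minimum")
        batch = img[None, :, :, None]
        residual = self.forward_batch(batch, train=False)[0, :, :, 0]
        residual = residual.astype(np.float64)
        return residual, img - residual

    def denoise(self, noisy: np.ndarray) -> np.ndarray:
        """Denoised estimate only (clipped back to [0, 1])."""
        _, denoised = self.forward(noisy)
        return np.clip(denoised, 0.0, 1.0)


def build_model(spec: DenoiserSpec, init_seed: int = 0, dtype=np.float64) -> ResidualDenoiser:
    """Allocate and initialize a :class:`ResidualDenoiser`.

    Conv weights use He-scaled Gaussian init; biases and BN beta start at 0,
    BN gamma at 1.  Deterministic given *init_seed*.
    """
    return ResidualDenoiser(spec, init_seed=init_seed, dtype=dtype)


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(model: ResidualDenoiser, path) -> None:
    """Write an ``.npz`` archive of layer-ordered tensors plus a JSON spec."""
    arrays = {}
    for i, (p, run) in enumerate(zip(model.params, model.running)):
        for k, v in p.items():
            arrays[f"layer{i:02d}/{k}"] = v
        if run is not None:
            arrays[f"layer{i:02d}/running_mean"] = run["mean"]
            arrays[f"layer{i:02d}/running_var"] = run["var"]
    manifest = json.dumps(
        {
            "depth": model.spec.depth,
            "channels": model.spec.channels,
            "residual": model.spec.residual,
            "dtype": model.dtype.name,
        }
    )
    arrays["manifest"] = np.frombuffer(manifest.encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> ResidualDenoiser:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        spec = DenoiserSpec(
            depth=manifest["depth"],
            channels=manifest["channels"],
            residual=manifest["residual"],
        )
        model = ResidualDenoiser(spec, init_seed=0, dtype=np.dtype(manifest["dtype"]))
        for i, (p, run) in enumerate(zip(model.params, model.running)):
            for k in p:
                p[k] = data[f"layer{i:02d}/{k}"]
            if run is not None:
                run["mean"] = data[f"layer{i:02d}/running_mean"]
                run["var"] = data[f"layer{i:02d}/running_var"]
    return model
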