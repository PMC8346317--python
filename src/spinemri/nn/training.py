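"""Training loop for the residual denoiser.

Training pairs are built on the fly: clean patches are cut from phantom (or
user-supplied) images, and every epoch corrupts them with *fresh* Rician
draws, so the network sees a new noise realization of each patch each time —
the standard trick that turns a small clean set into an effectively
unlimited noisy set.  The loss is mean squared error between the predicted
and the true noise map (the residual); minimizing it is equivalent to
minimizing MSE of the denoised image, and aligns with PSNR-based evaluation.

Determinism: the whole run is a pure function of ``config.seed`` — patch
extraction, parameter init, per-epoch noise and batch shuffling all draw
from generators spawned from that one integer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..noise import rician_sample
from ..phantoms import validate_image
from .model import DenoiserSpec, ResidualDenoiser, build_model
from .optim import AdamState, adam_step, sgd_step


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one training run.

    ``sigma_train`` may be a single noise scale or a sequence; each patch is
    corrupted at a scale drawn uniformly from the given set, which trains a
    single blind model across noise levels.
    """

    loss: str = "mse"
    patch_size: int = 40
    patches_per_image: int = 25
    batch_size: int = 16
    epochs: int = 15
    sigma_train: float | tuple[float, ...] = 0.1
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # per-epoch multiplicative decay (1.0 = constant)
    optimizer: str = "adam"
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.patch_size < 16:
            raise ValueError("patch_size must be >= 16")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "mse":
            raise ValueError("only the 'mse' loss is supported")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")

    @property
    def sigmas(self) -> tuple[float, ...]:
        s = self.sigma_train
        return tuple(s) if np.iterable(s) else (float(s),)


@dataclass
class TrainingResult:
    """Outcome of :func:`train`: the fitted model plus diagnostics."""

    model: ResidualDenoiser
    loss_trace: list[float]
    config: TrainingConfig

    @property
    def final_loss(self) -> float:
        return self.loss_trace[-1]


def extract_patches(
    images: list[np.ndarray], patch_size: int, n_per_image: int, rng: np.random.Generator
) -> np.ndarray:
    """Cut random patches from each image; returns (N, patch, patch)."""
    patches = []
    for img in images:
        arr = validate_image(img)
        h, w = arr.shape
        if h < patch_size or w < patch_size:
            raise ValueError(
                f"image {arr.shape} smaller than patch size {patch_size}"
            )
        for _ in range(n_per_image):
            r = int(rng.integers(0, h - patch_size + 1))
            c = int(rng.integers(0, w - patch_size + 1))
            patches.append(arr[r : r + patch_size, c : c + patch_size])
    return np.stack(patches)


def train(
    model: ResidualDenoiser | None,
    clean_images: list[np.ndarray],
    config: TrainingConfig,
    spec: DenoiserSpec | None = None,
) -> TrainingResult:
    """Fit the residual denoiser on Rician-corrupted patches.

    Pass an already-built *model* or a *spec* to build one from
    ``config.seed``.  Returns a :class:`TrainingResult` whose ``loss_trace``
    holds the mean per-epoch training loss.
    """
    if not clean_images:
        raise ValueError("need at least one clean image")
    dtype = np.dtype(config.dtype)
    if model is None:
        model = build_model(spec or DenoiserSpec(depth=7), init_seed=config.seed, dtype=dtype)

    ss = np.random.SeedSequence(config.seed)
    rng_patch, rng_epochs = [np.random.default_rng(c) for c in ss.spawn(2)]

    clean = extract_patches(
        clean_images, config.patch_size, config.patches_per_image, rng_patch
    ).astype(dtype)
    n = clean.shape[0]
    sigmas = np.asarray(config.sigmas, dtype=dtype)

    opt_state = AdamState(learning_rate=config.learning_rate)
    trace: list[float] = []
    for epoch in range(config.epochs):
        lr_epoch = config.learning_rate * config.lr_decay**epoch
        opt_state = replace(opt_state, learning_rate=lr_epoch)
        rng = np.random.default_rng(rng_epochs.integers(0, 2**31))
        sig = sigmas[rng.integers(0, len(sigmas), size=n)][:, None, None]
        noisy = rician_sample(clean, sig, rng).astype(dtype) if np.any(sig > 0) else clean.copy()
        target = noisy - clean  # the true noise map the network should predict
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = noisy[idx][:, :, :, None]
            tb = target[idx][:, :, :, None]
            pred, caches = model.forward_batch(xb, train=True)
            err = pred - tb
            loss = float(np.mean(err.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch start {start}"
                )
            epoch_loss += loss * len(idx)
            dresidual = (2.0 / err.size) * err
            grads = model.backward_batch(dresidual, caches)
            if config.optimizer == "adam":
                opt_state, model.params = adam_step(opt_state, model.params, grads)
            else:
                model.params = sgd_step(model.params, grads, lr_epoch)
        trace.append(epoch_loss / n)
    return TrainingResult(model=model, loss_trace=trace, config=config)
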