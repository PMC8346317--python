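"""Rician noise injection for magnitude MR images.

Magnitude MRI noise follows a Rician law: the complex k-space signal is
corrupted by independent Gaussian noise in the real and imaginary channels,
and taking the modulus gives

    y = sqrt((x + n1)^2 + n2^2),      n1, n2 ~ Normal(0, sigma^2).

At zero signal (x = 0) this reduces to a Rayleigh distribution with mode
sigma and mean sigma * sqrt(pi / 2); at high SNR it approaches a Gaussian
centred near sqrt(x^2 + sigma^2).  The noise is signal-dependent and biased
upward — mean(noisy) >= mean(clean) — which is what distinguishes MRI
denoising from the additive-Gaussian setting.

Clipping to [0, 1] is applied once, after the noise draw, and the clipped
pixel fraction is reported so that heavy-clipping regimes are visible to the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import validate_image


@dataclass(frozen=True)
class RicianParams:
    """Noise scale and seed for one Rician corruption draw."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class RicianResult:
    """A corrupted image plus bookkeeping about the final clipping step."""

    image: np.ndarray
    sigma: float
    clipped_fraction: float


def rician_sample(x: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one Rician corruption of the nonnegative signal array *x*.

    No clipping is applied; the output is the raw magnitude
    ``sqrt((x + n1)^2 + n2^2)`` and is therefore nonnegative by construction.
    """
    if np.any(np.asarray(sigma) < 0):
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    n1 = rng.normal(0.0, 1.0, size=x.shape) * sigma
    n2 = rng.normal(0.0, 1.0, size=x.shape) * sigma
    return np.sqrt((x + n1) ** 2 + n2**2)


def add_rician_noise(
    img: np.ndarray,
    params: RicianParams,
    clip: bool = True,
) -> RicianResult:
    """Corrupt a clean [0, 1] image with Rician noise.

    With ``sigma == 0`` the output equals the input exactly.  Clipping to
    [0, 1] happens once, at the very end, and the fraction of clipped pixels
    is returned alongside the image.
    """
    clean = validate_image(img)
    if params.sigma == 0.0:
        return RicianResult(image=clean.copy(), sigma=0.0, clipped_fraction=0.0)

    rng = np.random.default_rng(params.seed)
    noisy = rician_sample(clean, params.sigma, rng)
    if clip:
        clipped = float(np.mean((noisy < 0.0) | (noisy > 1.0)))
        noisy = np.clip(noisy, 0.0, 1.0)
    else:
        clipped = 0.0
    return RicianResult(image=noisy, sigma=params.sigma, clipped_fraction=clipped)
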