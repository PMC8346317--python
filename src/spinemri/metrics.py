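"""Image-quality metrics and the denoiser evaluation harness.

PSNR and SSIM are the two standard full-reference metrics for denoising
benchmarks.  PSNR is ``10 * log10(peak^2 / MSE)`` in decibels; SSIM is the
windowed luminance/contrast/structure comparison with the de facto standard
constants (Gaussian window of width 11, sigma 1.5, k1 = 0.01, k2 = 0.03).
Images in this package live in [0, 1], so the peak defaults to 1.0.

The harness runs a set of denoisers over a factorial grid of phantoms and
noise scales, feeding *byte-identical* noisy inputs to every method so the
comparison is paired.  Identity (no-op) and Gaussian-blur baselines are
built in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.metrics import structural_similarity

from .noise import RicianParams, add_rician_noise
from .phantoms import validate_image

Denoiser = Callable[[np.ndarray], np.ndarray]


def psnr(reference: np.ndarray, test: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB.

    Identical images have zero MSE; the documented sentinel ``math.inf`` is
    returned rather than raising.
    """
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    if peak <= 0:
        raise ValueError("peak must be > 0")
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def ssim(
    reference: np.ndarray,
    test: np.ndarray,
    window: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
    peak: float = 1.0,
) -> float:
    """Mean structural similarity over a Gaussian-weighted sliding window."""
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > min(ref.shape):
        raise ValueError(f"window {window} exceeds image extent {min(ref.shape)}")
    return float(
        structural_similarity(
            ref,
            tst,
            win_size=window,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=k1,
            K2=k2,
            data_range=peak,
        )
    )


# -- built-in baseline denoisers ------------------------------------------


def identity_denoiser(noisy: np.ndarray) -> np.ndarray:
    """No-op baseline: returns the noisy input unchanged."""
    return np.asarray(noisy, dtype=np.float64)


def gaussian_blur_denoiser(sigma: float = 1.0) -> Denoiser:
    """Classical baseline: isotropic Gaussian smoothing of strength *sigma*."""

    def _blur(noisy: np.ndarray) -> np.ndarray:
        return gaussian_filter(np.asarray(noisy, dtype=np.float64), sigma=sigma)

    return _blur


# -- evaluation harness ----------------------------------------------------


@dataclass(frozen=True)
class MetricReport:
    """Mean PSNR/SSIM of one method at one noise scale."""

    method: str
    sigma: float
    psnr_db: float
    ssim: float
    n_images: int
    per_image_psnr: tuple[float, ...]
    per_image_ssim: tuple[float, ...]


def evaluate_harness(
    denoisers: dict[str, Denoiser],
    sigmas: list[float],
    phantoms: list[np.ndarray],
    seed: int = 0,
) -> list[MetricReport]:
    """Compare denoisers across noise levels on a shared noisy set.

    For every (phantom, sigma) pair one Rician corruption is drawn and the
    *same* noisy array is handed to every method, so per-image metric
    differences reflect the methods alone.  Deterministic given *seed*.
    """
    if not denoisers or not sigmas or not phantoms:
        raise ValueError("need at least one denoiser, one sigma and one phantom")
    clean = [validate_image(p) for p in phantoms]
    ss = np.random.SeedSequence(seed)
    noise_seeds = np.array(
        [c.generate_state(1)[0] % (2**31) for c in ss.spawn(len(sigmas) * len(clean))]
    ).reshape(len(sigmas), len(clean))

    reports: list[MetricReport] = []
    for si, sigma in enumerate(sigmas):
        noisy_set = [
            add_rician_noise(img, RicianParams(sigma=sigma, seed=int(noise_seeds[si, pi]))).image
            for pi, img in enumerate(clean)
        ]
        for name, fn in denoisers.items():
            ps, ss_vals = [], []
            for img, noisy in zip(clean, noisy_set):
                out = np.clip(fn(noisy.copy()), 0.0, 1.0)
                ps.append(psnr(img, out))
                ss_vals.append(ssim(img, out))
            reports.append(
                MetricReport(
                    method=name,
                    sigma=float(sigma),
                    psnr_db=float(np.mean(ps)),
                    ssim=float(np.mean(ss_vals)),
                    n_images=len(clean),
                    per_image_psnr=tuple(ps),
                    per_image_ssim=tuple(ss_vals),
                )
            )
    return reports


def reports_to_frame(reports: list[MetricReport]) -> pd.DataFrame:
    """Tabulate harness reports (one row per method x sigma)."""
    return pd.DataFrame(
        {
            "method": [r.method for r in reports],
            "sigma": [r.sigma for r in reports],
            "psnr_db": [r.psnr_db for r in reports],
            "ssim": [r.ssim for r in reports],
            "n_images": [r.n_images for r in reports],
        }
    )


def plot_reports(reports: list[MetricReport], path) -> None:
    """PSNR and SSIM vs noise scale, one line per method (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = reports_to_frame(reports)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for metric, ax in zip(("psnr_db", "ssim"), axes):
        for method, grp in df.groupby("method"):
            grp = grp.sort_values("sigma")
            ax.plot(grp["sigma"], grp[metric], marker="o", label=method)
        ax.set_xlabel("noise scale sigma")
        ax.set_ylabel(metric)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
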