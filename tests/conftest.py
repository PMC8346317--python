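import numpy as np
import pytest

from spinemri.metrics import psnr, ssim
from spinemri.nn.model import DenoiserSpec
from spinemri.nn.training import TrainingConfig, train
from spinemri.noise import RicianParams, add_rician_noise
from spinemri.phantoms import generate_phantom, phantom_bank


@pytest.fixture(scope="session")
def desk_training():
    """One desk-scale training run shared by the slower end-to-end tests.

    Depth-7 model, 200 clean 40x40 patches from 8 phantoms, Rician sigma
    0.1, 15 epochs of Adam; held-out phantoms evaluated at the same sigma.
    """
    train_images = phantom_bank(100, 8, 64, 64, 6)
    held_images = phantom_bank(999, 4, 64, 64, 6)
    config = TrainingConfig(
        patch_size=40,
        patches_per_image=25,
        batch_size=16,
        epochs=15,
        sigma_train=0.1,
        learning_rate=1e-3,
        seed=0,
    )
    result = train(None, train_images, config, spec=DenoiserSpec(depth=7))
    return result, train_images, held_images


@pytest.fixture(scope="session")
def desk_gains(desk_training):
    """Held-out PSNR/SSIM of noisy vs denoised images at sigma = 0.1."""
    result, _, held = desk_training
    rows = []
    for i, img in enumerate(held):
        noisy = add_rician_noise(img, RicianParams(sigma=0.1, seed=5000 + i)).image
        den = result.model.denoise(noisy)
        rows.append(
            {
                "psnr_noisy": psnr(img, noisy),
                "psnr_denoised": psnr(img, den),
                "ssim_noisy": ssim(img, noisy),
                "ssim_denoised": ssim(img, den),
            }
        )
    return rows


@pytest.fixture()
def phantom64():
    return generate_phantom(seed=1, height=64, width=64, n_structures=5)
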