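# spinemri

Rician-noise denoising for lumbar spine MRI with a from-scratch residual
convolutional network, plus the clinical analysis layer that typically
consumes such images: facet-joint asymmetry and disc-height grading rules,
and rank-correlation statistics over an ordinal patient cohort.

The package is aimed at researchers who want a fully inspectable,
CPU-sized reference implementation of the magnitude-MRI denoising pipeline
— noise model, network, optimizers and metrics are all plain numpy with
hand-derived gradients, verified against independent oracles — together
with a calibrated cohort simulator for exercising the downstream
ordinal-statistics analysis end to end without patient data.

## What is inside

**Noise model.** Magnitude MR noise is Rician:
`y = sqrt((x + n₁)² + n₂²)` with `n₁, n₂ ~ N(0, σ²)` — Rayleigh at zero
signal, approximately Gaussian near `sqrt(x² + σ²)` at high SNR, and biased
upward everywhere.

**Denoiser.** A residual network learns the noise map `F(x)` and recovers
the clean estimate through the identity skip, `denoised = noisy − F(x)`.
Default depth 15 (conv 3×3×1×64 + ReLU; 13 × [conv 3×3×64×64 + batch norm
+ ReLU]; conv 3×3×64×1), stride 1, zero padding 1, 482,945 parameters.
Reduced depths (3, 7) are first-class for CPU-scale work. Training
minimizes MSE on the residual with SGD or full Adam (bias-corrected first
and second moments), all implemented from first principles.

**Metrics.** PSNR (`10·log₁₀(peak²/MSE)` dB) and windowed SSIM, plus a
paired evaluation harness that feeds byte-identical noisy inputs to every
method across a σ grid.

**Grading rules.** Facet tropism: asymmetric iff the left–right facet
angle difference strictly exceeds 7°. Disc height against level-specific
normal values (midpoint of the published ranges by default): > 80 % slight
decrease, 60–80 % moderate decrease, ≤ 60 % gap collapse.

**Statistics.** Spearman rank correlation with midranks for ties (vector
and closed-form grouped-table routes), Pearson χ² on contingency tables,
percentage summaries, and a report builder producing the standard
facet-grade × herniation-category, asymmetry-by-level, grade-distribution,
age/sex and symptom-frequency tables.

**Synthetic data.** Piecewise-constant spine-like phantoms for the imaging
leg, and a Gaussian-copula patient cohort (n patients × 3 lumbar levels)
whose disc-grade/facet-grade Spearman correlation is calibrated exactly in
population to a requested target (default 0.753) and whose herniation
category margins can be pinned exactly (52/69/6 of 127).

## Worked example

```python
import numpy as np
from spinemri import (
    CohortParams, DenoiserSpec, RicianParams, TrainingConfig,
    add_rician_noise, generate_cohort, generate_phantom, grade_cohort,
    psnr, ssim, train,
)
from spinemri.phantoms import phantom_bank
from spinemri.stats import build_report

# --- imaging leg -------------------------------------------------------
clean = generate_phantom(seed=1, height=64, width=64, n_structures=5)
noisy = add_rician_noise(clean, RicianParams(sigma=0.1, seed=2)).image
print(f"noisy PSNR {psnr(clean, noisy):.2f} dB, SSIM {ssim(clean, noisy):.3f}")

config = TrainingConfig(patch_size=40, patches_per_image=25, batch_size=16,
                        epochs=15, sigma_train=0.1, seed=0)
result = train(None, phantom_bank(100, 8, 64, 64, 6), config,
               spec=DenoiserSpec(depth=7))
denoised = result.model.denoise(noisy)
print(f"denoised PSNR {psnr(clean, denoised):.2f} dB, SSIM {ssim(clean, denoised):.3f}")

# --- cohort leg --------------------------------------------------------
cohort = generate_cohort(CohortParams(n_patients=127, fixed_margins=True, seed=3))
report = build_report(grade_cohort(cohort))
rho = report.correlations["disc_grade_vs_facet_grade"]
print(f"disc vs facet Spearman rho = {rho.rho:.3f} (n = {rho.n}, p = {rho.p_value:.2e})")
```

Output:

```
noisy PSNR 20.39 dB, SSIM 0.463
denoised PSNR 25.15 dB, SSIM 0.760
disc vs facet Spearman rho = 0.785 (n = 381, p = 6.09e-81)
```

The network recovers ≈ 5 dB of PSNR and over half the lost structural
similarity at σ = 0.1 after two minutes of CPU training; the simulated
cohort tracks the calibrated disc–facet association (0.753 in population;
0.785 in this 127-patient draw) and pins the 52/69/6 herniation-category
margins exactly.

## Command line

```bash
spinemri simulate-images --seed 1 --n-images 4 --out imgs/
spinemri add-noise --in imgs/clean_00.png --out noisy.png --sigma 0.1
spinemri train --depth 7 --epochs 15 --out model.ckpt.npz
spinemri denoise --model model.ckpt.npz --in noisy.png --out denoised.png
spinemri evaluate --model model.ckpt.npz --out eval/
spinemri simulate-cohort --n-patients 127 --out cohort.csv
spinemri grade --in cohort.csv --out graded.csv
spinemri analyze --in graded.csv --out report/
spinemri run-all --seed 1 --out pipeline_out/
```

`run-all` executes every stage into one artifact directory with a manifest
(config hash, per-stage seeds, artifact hashes) sufficient to reproduce the
run bit for bit.

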