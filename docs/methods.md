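# Methods

This note documents the models, rules and numerical choices behind
`spinemri`: what is simulated, what is fitted, what is computed, and where
the genuinely open design decisions were settled.

## 1. The denoising problem

Magnitude MR images carry Rician noise: the complex signal is corrupted by
independent zero-mean Gaussian noise of scale σ in its real and imaginary
channels, and the magnitude operation produces

    y = sqrt((x + n₁)² + n₂²),   n₁, n₂ ~ N(0, σ²).

At zero signal this is a Rayleigh law (mean σ·√(π/2)); at high SNR it is
approximately Gaussian around √(x² + σ²). Two properties matter for
denoising: the noise is *signal-dependent*, and it is *biased upward*
(E[y] ≥ x), so the additive-Gaussian toolbox does not transfer unchanged.
The injector draws the two Gaussian channels explicitly, never an additive
approximation. Clipping to [0, 1] is applied exactly once, after the draw,
and the clipped pixel fraction is reported so heavy-clipping regimes
(large σ, bright tissue) are visible rather than silent.

## 2. The residual network

The denoiser is a plain convolutional stack that learns the *noise map*:
with the desired clean mapping written H(x), the network fits the residual
F(x) = H(x) − x and the estimate is recovered through the identity skip,
here with the sign convention that the network predicts the noise and

    denoised = noisy − F̂(noisy).

Residual fitting avoids the vanishing-gradient failure of deep plain
stacks and is the standard formulation for CNN denoisers.

Default architecture (depth 15):

| layers | shape | extras |
|---|---|---|
| 1 (input) | 3×3×1×64 conv | ReLU |
| 2–14 (hidden, 13 of them) | 3×3×64×64 conv | batch norm + ReLU |
| 15 (output) | 3×3×64×1 conv | linear |

All convolutions are stride 1 with zero padding 1 so spatial dimensions are
preserved end to end — a *requirement* of the elementwise skip connection,
which is why no pooling appears anywhere in the stack. Conv biases are
retained in every layer, including the batch-normalized ones where they are
redundant with the BN shift β; the documented parameter count (482,945 for
depth 15: 480,384 weights + 897 biases + 1,664 BN parameters) follows this
convention. Reduced depths (3, 7) keep the same input/output layers and
shrink the hidden stack; they are first-class configurations so CPU-scale
training stays in minutes. Weight init is He-scaled Gaussian (std
√(2/fan-in)), γ = 1, β = 0, biases 0.

Batch normalization standardizes each channel by the batch mean and biased
variance, then applies the learned affine (γ, β); ε defaults to 1e-5.
Inference uses running statistics accumulated by exponential moving average
with momentum 0.1. A training batch of size 1 is rejected (its variance
carries no information), and a numerically zero-variance batch maps to β
exactly rather than amplifying rounding noise through 1/√ε.

The whole network, its gradients, and both optimizers are implemented
directly in numpy. Backpropagation is hand-derived per layer (convolution
via shift-and-matmul over the nine kernel offsets; BN differentiating both
batch moments) and verified against central finite differences; the only
parameters whose analytic gradient legitimately differs from the numeric
quotient are the BN-absorbed hidden conv biases, whose true gradient is
exactly zero.

### Optimizers

SGD is the textbook single step p ← p − η·∇C. Adam keeps exponentially
weighted first and second gradient moments

    m_t = β₁ m_{t−1} + (1−β₁) g_t,
    v_t = β₂ v_{t−1} + (1−β₂) g_t²,

with bias corrections m̂ = m_t/(1−β₁ᵗ), v̂ = v_t/(1−β₂ᵗ) and update
p ← p − η·m̂/(√v̂ + ς). The second-moment recursion is algebraically the
geometric sum (1−β₂)Σᵢ β₂^{t−i} gᵢ², and the correction makes v̂ = g²
exact for a static gradient at every t — both identities are unit-tested
against an explicit summation oracle. Defaults: β₁ = 0.9, β₂ = 0.999,
ς = 1e-8, η = 1e-3. ς = 0 is admissible only in the static-gradient limit;
the default keeps the update defined for vanishing v̂. An optional
per-epoch multiplicative learning-rate decay (`lr_decay`) is available for
longer runs; the desk-scale defaults keep it at 1 (constant rate).

### Training protocol

The loss is mean squared error between the predicted and the true noise
map, equivalent to MSE of the denoised image and consistent with
PSNR-based evaluation. Clean patches are cut once from the input images;
every epoch corrupts them with *fresh* Rician draws, so a small clean set
yields an effectively unlimited noisy stream. `sigma_train` may be a set,
in which case each patch draws its σ uniformly from the set and the model
is blind across that range. Training is a pure function of the config seed
(patch positions, init, noise, shuffling all derive from it). A non-finite
loss aborts with the epoch/batch named.

Desk-scale defaults, used by the test suite and the acceptance script:
depth 7, 200 patches of 40×40 cut from 8 phantoms, batch 16, Adam 1e-3,
15 epochs at σ = 0.1 (float32 arithmetic; float64 in gradient checks).
This trains in roughly two minutes on one CPU core and improves held-out
PSNR by ≈ 4–5 dB and SSIM by ≈ 0.25 over the noisy input at σ = 0.1. The
cross-noise-level comparison trains one σ-matched depth-3 model per grid
point (the non-blind protocol): at the lowest σ the noisy input is already
good (≈ 26 dB), and a σ-matched model clears it comfortably where a
desk-scale blind model needs substantially longer training to stop
oversmoothing.

## 3. Phantoms: what they emulate and what they do not

Phantoms are piecewise-constant compositions of ellipses ("vertebral
bodies"), thin bands ("discs") and paired disks ("facet wedges") at
distinct intensity plateaus on a dark background. They give a denoising
benchmark a perfectly known clean signal with sharp edges and flat
regions — the two features that matter for judging noise removal versus
oversmoothing. They do *not* emulate anatomy, partial-volume texture,
k-space acquisition, coil inhomogeneity or 3-D context; a gain measured
here demonstrates that the training loop and architecture work, not that
the trained weights transfer to clinical MRI.

## 4. Image quality metrics

PSNR = 10·log₁₀(peak²/MSE) dB, peak fixed at 1.0 for [0, 1] images;
identical images report `inf` as a documented sentinel. SSIM uses the de
facto standard constants: Gaussian window of width 11 (σ_w = 1.5),
k₁ = 0.01, k₂ = 0.03, computed via scikit-image with population (not
sample) covariance normalization. For two constant images the variance
terms vanish and SSIM reduces to the luminance term
(2μ₁μ₂ + C₁)/(μ₁² + μ₂² + C₁), a closed form the tests pin.

The evaluation harness draws one Rician corruption per (phantom, σ) cell
and feeds the *identical* noisy array to every method, so method
differences are paired; identity and Gaussian-blur baselines are built in.
The σ grid {0.05, 0.10, 0.15} is a package default, chosen to span
visually mild to severe corruption of [0, 1] phantoms.

## 5. Clinical grading rules

Facet tropism: a segment is asymmetric iff |left − right| > 7°, strictly;
exactly 7° is symmetric. Angles outside (0°, 90°) are rejected as
anatomically impossible.

Disc height: the measured height is divided by a level-specific normal
reference; ratio > 80 % → slight decrease, 60 % < ratio ≤ 80 % → moderate
decrease, ratio ≤ 60 % → gap collapse. The published normal values are
*ranges* (L3/4: 1.073–1.247 cm, L4/5: 1.18–1.272 cm, L5/S1:
0.939–1.121 cm) with no scalar stated, so the reference defaults to the
range midpoint with `lower`/`upper` selectable for sensitivity analysis.
Equality at 80 % or 60 % falls to the severer class (reading "higher than"
strictly); under this convention the three classes partition (0, ∞), and
no "normal" class is emitted (none is defined by the three-way rule).
Facet grades 0–3 and disc grades I–V are ordinal inputs scored elsewhere;
this package never derives them from images.

## 6. Cohort simulator

Each of n patients contributes one record per level (L3/4, L4/5, L5/S1).
A one-factor Gaussian copula ties the ordinal variables together: each
record has a latent severity s ~ N(0,1); the disc and facet latents load
on s with equal loadings √|r|, and grades arise by cutting each latent at
the quantiles of its marginal distribution. The latent correlation r is
calibrated by bisection so that the *population* Spearman of the
discretized pair equals the requested target. That population value is
computed exactly — bivariate-normal rectangle probabilities over the
threshold grid, then the weighted Pearson correlation of the population
midrank scores — so calibration involves no Monte-Carlo loop, and the
empirical Spearman at n = 10,000 patients lands within ±0.02 of the
target. A requested |ρ| above the attainable maximum under the configured
marginals (≈ 0.9 for the default grade frequencies) raises a calibration
error rather than silently saturating.

Defaults are matched to the study population the simulator emulates:
herniation category frequencies (52, 69, 6)/127; facet-grade marginals
(36, 56, 21, 14)/127 (the published row totals); disc-grade marginals
(0.07, 0.17, 0.26, 0.32, 0.18) with grade IV modal (reported 31.76 %); the
disc–facet Spearman target 0.753; residual-symptom prevalence 81/127 with
the age distribution peaked at 61–70 years; and a severe-urinary-disorder
symptom probability of 0.7196 among symptomatic patients. The herniation
propensity loads on the patient's mean severity (loading 0.6), LDH
patients receive a mean shift (default 3.5°) in their half-normal
left–right facet angle difference (scale 4°), and disc height follows disc
grade through mean height ratios (1.00, 0.92, 0.84, 0.72, 0.55) with 5 %
Gaussian scatter — so asymmetry, herniation, degeneration and height are
mutually associated the way the analysis assumes. In fixed-margin mode the
exact category multiset (e.g. 52/69/6 of 127) is assigned to patients in
propensity rank order, which pins the published column totals exactly
while preserving the association. All randomness in a call flows from the
single seed; two calls with equal parameters produce byte-identical CSVs.

The simulator produces the *statistical* structure the analysis consumes,
nothing more: its agreement with published summary statistics shows the
analysis pipeline is correct, not that the generating mechanism is
clinically realistic.

## 7. Rank statistics

Spearman's ρ is the Pearson correlation of midranks (average ranks over
ties); p-values use the large-sample t approximation, with an exact
permutation option for n < 10. Rank correlations carry α = 0.005 and
χ² tests α = 0.05 as metadata, with no multiplicity correction — matching
the analysis protocol the package mirrors.

For grouped ordinal data the midrank of every subject in a category is a
function of the margins alone, so ρ is computed from a contingency table in
closed form (weighted Pearson of row/column midranks). Its exact equality
with the expand-then-rank route is a tested invariant, and the two routes
are implemented independently (closed form in the library, expansion in the
tests). The χ² test is Pearson's, expected counts from margins, no
continuity correction; degenerate margins are rejected with the offending
category named.

Category encodings default to decreasing severity LDH = 1, bulging = 2,
none = 3. The *sign* of any correlation against herniation category is a
pure artifact of this (configurable) choice. Notably, expanding the
published facet-grade × category counts under any monotone encoding yields
|ρ| < 0.15 — the grouped table does not support the strong negative
correlation reported alongside it, so published patient-level correlations
are treated solely as simulator calibration targets, never as quantities
this package claims to reproduce.

Percentages render as "count (percent)" with two half-even decimals and
explicit denominators. Report tables use per-column denominators
(the source tables the renderer mirrors divide every cell by one fixed
column total, which is documented here as a divergence, not replicated).
The per-patient contingency tables use each patient's *index level* — the
level with the worst disc grade, ties toward the more cranial level — so
that 127 patients yield 127 table entries from 381 records.

## 8. Problem sizes and determinism

Default suites run at: 200 training patches / 15 epochs (denoiser), 10⁵
samples (noise-law calibration), 10,000 patients (correlation recovery),
127 patients (fixed-margin cohort), 500 random vectors (rank-statistic
oracles). These sizes were chosen so the whole suite completes in a few
minutes on a single CPU core while keeping every stochastic check at least
3 standard errors away from its threshold. Every stochastic component
takes an explicit integer seed; the pipeline derives per-stage seeds from
one global seed via `SeedSequence` spawning in fixed stage order, and the
run manifest records config hash, stage seeds and artifact hashes so a run
can be reproduced bit-for-bit.

## 9. Known limitations

* Phantom realism as in §3; metric gains do not certify clinical utility.
* The desk-scale network is depth 7 and CPU-sized; the depth-15 default is
  validated structurally (parameter count, gradients) but not trained to
  convergence by the test suite.
* The Rician model assumes spatially constant σ and no spatial noise
  correlation (single-coil magnitude reconstruction).
* The cohort copula is one-factor; real degeneration cascades are richer
  (age confounding, level-to-level coupling within a patient beyond the
  shared factor).
* Spearman p-values for the grouped tables use the t approximation, which
  is mildly anticonservative under heavy ties at small n.
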