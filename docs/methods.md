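# Methods

## Model

BL-INR treats one noisy DWI volume as samples of a continuous function over
the image domain Ω ⊂ ℝ³ and fits a multilayer perceptron g_θ to regress each
voxel's clean intensity from a per-voxel descriptor.  The fit is
self-supervised: the loss is the mean squared error against the noisy target
itself, L = (1/|Ω|) Σ_p (I_noisy(p) − g_θ(f(p)))².  Denoising emerges from two
capacity constraints rather than from clean supervision:

1. **Band-limited positional encoding.**  Coordinates are normalized to
   [−1, 1] per axis (index 0 → −1, index n−1 → +1, voxel-centre semantics;
   singleton axes map to 0).  For frequencies ω_1 … ω_K equally spaced on
   [1, ω_max] the encoding emits sin(ω_k p_i)·sinc(ω_k σ) and
   cos(ω_k p_i)·sinc(ω_k σ) with σ = 1/ω_max, where sinc(x) = sin(πx)/(πx).
   The window is exactly zero at ω_max and strictly decreasing below it, so
   the feature basis simply does not span frequencies at or past the cutoff.
   Numerically the attenuation is evaluated as sinc(ω_k/ω_max) — identical
   algebraically, but the cutoff argument is exactly 1 in floating point, so
   the zero is exact rather than ~1e−16; the sinc implementation also pins
   exact zeros at nonzero integer arguments.
2. **Cross-contrast priors.**  The descriptor appends flattened patches
   (default 3×3×3, x-fastest order, edge-replicated at borders) taken at the
   same voxel from every other-b-value volume (ascending b) and every
   anatomical contrast (declared order).  Signal is correlated across these
   volumes while their noise is independent, so patch features vote for the
   shared structure.  Anatomical volumes on a different grid are first
   resampled by trilinear interpolation under an axis-aligned
   shape-and-spacing correspondence (full NIfTI s-form affines are a
   documented non-goal).

The assumptions this rests on: spatial smoothness of the underlying signal,
weak spatial correlation of the noise, and weak noise correlation *between*
acquisitions of the same session.  Structured artifacts (motion, ghosting,
spatially correlated parallel-imaging noise) violate them and are out of
scope.

## Network and optimisation

g_θ is a plain MLP: `depth` hidden layers (default 4) of `hidden_dim` units
(default 1024) with ReLU activations and a linear scalar head.  ReLU is
chosen because the encoding already provides the sinusoidal basis; periodic
activations would duplicate its role.  Initialisation is uniform fan-in
(U(±1/√fan_in)) from a seeded generator; forward, backward and Adam
(β = 0.9/0.999, ε = 1e−8) are implemented directly in NumPy, which at these
widths runs comfortably on one CPU core and keeps the whole pipeline
dependency-light and bit-reproducible.

Training defaults follow the published regime: learning rate 4×10⁻⁴ annealed
to zero by a cosine schedule over the total step count, 20 epochs, where one
epoch is one seed-shuffled full pass over all voxels in mini-batches of 4096.
The target and each prior volume are independently normalised by their own
99th-percentile intensity before training (robust to hot voxels; scales are
recorded on the result and the output is rescaled back).  No masking is
applied: the loss runs over all of Ω.  Negative outputs are kept during
training and floored at zero only on NIfTI export.  One independent model is
trained per target b-value; in `denoise_series` each target's seed derives
from the configured seed plus the rank of its b-value, so results are
invariant to the order volumes are listed.

**Step budget at reduced scale.**  An "epoch" count is only meaningful
relative to the volume size: 20 epochs over a clinical volume is tens of
thousands of Adam steps, while 20 epochs over a 32³ test volume is 160.  The
end-to-end suites therefore run 60 epochs (150 for the patch-9 shift study,
whose relative-SSIM comparison needs a converged baseline) on 24³–32³
volumes with hidden width 64–128 and K_ω = 8 — the same mechanism at desk
scale, with a comparable optimisation budget per voxel.

## Key parameters

| parameter | default | meaning / guidance |
|---|---|---|
| `encoding.omega_max` | 20 | cutoff frequency (cycles per normalized unit). Performance is an inverted U: too low over-smooths, too high re-admits noise; ~20 is robust across settings. |
| `encoding.count` | round(ω_max) | number of frequencies; default gives integer frequencies at unit spacing. |
| `patch_size` | 3 | prior patch width (voxels, odd). 3 is the accuracy optimum; larger patches trade accuracy for tolerance to registration error. |
| `training.learning_rate` | 4e−4 | Adam initial rate, cosine-annealed to 0. |
| `training.epochs` | 20 | full passes over the voxel grid. |
| `training.batch_voxels` | 4096 | mini-batch size. |
| `training.normalization_percentile` | 99 | per-volume intensity scale. |
| `hidden_dim` / `depth` | 1024 / 4 | MLP width and hidden-layer count. |

## Synthetic data

`make_diffusion_phantom` builds a quantitative tube phantom: z-aligned
cylinders with per-tube S0 and ADC inside a uniform background, multi-b
volumes following S(b) = S0·exp(−b·ADC) exactly, plus the voxel-wise ADC
ground truth (overlapping tubes are rejected).  `make_brainlike_maps`
thresholds seeded Gaussian-smoothed noise into a few tissue classes with
piecewise-constant S0/ADC — a fixture with brain-like edge and frequency
content, not an anatomical claim.  `make_anatomical_companion` derives a
co-registered contrast by monotone intensity remapping.

Noise is Rician: M = √((A+n₁)² + n₂²) with n ~ N(0, σ²), seeded.  SNR is
defined as (mean clean foreground intensity)/σ — foreground defaults to
strictly positive voxels — so a requested SNR fixes σ.  Simulated studies
follow the protocol of degrading only the *target* volume to the test SNR
while companion volumes keep native acquisition quality (SNR 10 here): the
priors of a real session are not re-noised when one b-value is hard to
acquire cleanly.  The noise-floor correction defaults to the mean-based
Â = √(max(M² − σ², 0)), whose expectation tracks A closely down to A ≈ 2σ;
the second-moment variant √(max(M² − 2σ², 0)) (unbiased in E[M²] but biased
low in the mean) is selectable.  Registration error is emulated by
integer-voxel shifts with edge replication.

What passing these tests does *not* show: performance on real scanner data
with spatially varying coil sensitivity, correlated noise, motion, or
vendor preprocessing — the generator deliberately models none of those.

## Evaluation

PSNR = 10·log10(range²/MSE) (+inf sentinel for identical inputs; range
defaults to the reference maximum and must be held fixed across compared
methods).  SSIM uses k1 = 0.01, k2 = 0.03, uniform 7-wide windows, n−1
covariance normalisation and border cropping, computed per axial slice and
averaged (a 3-D windowed mode exists); the implementation is independent and
is tested to ≤1e−6 against scikit-image.  For simulated comparisons the
Rician floor is removed from both the noisy input and the denoised output
before scoring, mirroring how near-noise-free references are used.
Reference-free assessment reports ROI mean (fidelity) and sample standard
deviation (noise), the criterion used when no clean image exists.  ADC
fitting is unweighted log-linear OLS per voxel over the b-values with S > 0;
voxels with fewer than two usable samples are flagged invalid, and negative
fitted ADCs are kept but flagged.  Tube errors are reported both per tube
(then averaged, tubes weighted equally) and pooled over voxels.

## Numerical and design choices

* Descriptors and training run in float32; losses and exported volumes in
  float64/float32 respectively.  Metrics run in float64.
* Cosine annealing goes to exactly 0 at the final step; with scheduling off
  the rate is constant.
* `depth` counts hidden layers; the scalar head is separate (depth 1 = one
  hidden layer + head).
* Percentile normalisation makes training exactly equivariant to global
  intensity scaling of the target.
* Patch boundary handling, shift vacancies and out-of-extent resampling all
  use edge replication, never zero fill, so the network cannot mistake
  padding for structure.
* Degenerate cases: ω_max = 1 forces a single frequency; a constant volume
  normalises by scale 1 instead of 0; epochs = 0 returns the untrained
  model's output with its evaluated loss.

## Limitations

Per-volume training costs minutes of CPU per target b-value at full width —
the price of needing no training corpus.  Only axis-aligned grid
correspondence is supported for resampling; oblique acquisitions need
upstream resampling.  The Wilcoxon signed-rank utility is provided for
multi-case comparisons but no statistical gate is built in.  Hash-grid and
wavelet encodings are deliberately not implemented; the encoding interface
accepts only `bandlimited`, `fourier`, `identity`.
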