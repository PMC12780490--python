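# blinr — band-limited INR denoising for diffusion-weighted MRI

Diffusion-weighted imaging (DWI) trades signal for diffusion contrast: the
stronger the diffusion weighting (b-value), the lower the SNR, and the less
reliable any apparent-diffusion-coefficient (ADC) map fitted from the images.
`blinr` implements **BL-INR**, a self-supervised denoiser that represents each
DWI volume as a continuous function learned by a small coordinate MLP — with a
frequency cutoff built into its input encoding so the network physically
cannot learn the noise it is trained on.

## The method

For each voxel p (coordinates normalized to [−1, 1]³) the network g_θ
predicts the clean intensity from a descriptor

    f(p) = [ φ(p),  P_b1(p), …, P_bK(p),  P_s1(p), …, P_sM(p) ]

* **φ(p)** is the band-limited positional encoding.  With frequencies ω_k
  equally spaced on [1, ω_max] and σ = 1/ω_max,

      φ_sin(i,k) = sin(ω_k p_i) · sinc(ω_k σ),
      φ_cos(i,k) = cos(ω_k p_i) · sinc(ω_k σ),

  where sinc(x) = sin(πx)/(πx).  The sinc window is exactly zero at the
  cutoff (sinc(1) = 0) and attenuates monotonically below it — an ideal
  low-pass filter on the feature spectrum, so high-frequency noise has no
  basis function to latch onto.
* **P_b(p)** are flattened 3×3×3 patches from the other-b-value volumes and
  **P_s(p)** from co-registered anatomical contrasts (T1/T2, trilinearly
  resampled to the DWI grid).  True anatomy is correlated across contrasts
  while their noise realizations are independent, so these priors sharpen
  structure without importing the target's noise.

Training is self-supervised on the noisy target alone (MSE loss over all
voxels, Adam at 4×10⁻⁴ with cosine annealing) — one dedicated model per
target b-value, no clean references and no training corpus.  ADC maps are
then fitted voxel-wise by log-linear least squares on S(b) = S0·exp(−b·ADC).

The package also ships the synthetic machinery to exercise all of this end to
end: a tube phantom with known ADC values, brain-like piecewise-smooth
volumes, Rician noise injection at controlled SNR with the matching
noise-floor correction, PSNR/SSIM/ROI metrics, and sweep runners for ω_max,
patch size and registration-shift robustness.

## Worked example

Simulate a 24³ three-b-value tube phantom at SNR 3, denoise the b = 0 volume
with the other two b-values as priors, and score against the clean reference:

```bash
blinr simulate --size 24 --b-values 0,500,1000 --snr 3 --seed 7 --outdir sim
cat > cfg.yaml <<EOF
encoding:
  omega_max: 20
  count: 8
training:
  epochs: 60
  hidden_dim: 64
EOF
blinr denoise --target sim/noisy_b0.nii.gz \
    --prior b500=sim/noisy_b500.nii.gz --prior b1000=sim/noisy_b1000.nii.gz \
    --config cfg.yaml --seed 0 --out denoised_b0.nii.gz
blinr evaluate --ref sim/clean_b0.nii.gz --test sim/noisy_b0.nii.gz
blinr evaluate --ref sim/clean_b0.nii.gz --test denoised_b0.nii.gz
```

On this run the noisy input scores `psnr 21.0123 / ssim 0.934241` and the
denoised output `psnr 22.3038 / ssim 0.957946`: about +1.3 dB and +0.024 SSIM
recovered purely self-supervised, before any noise-floor correction (the
simulation writes σ = 93.75 into `sim/manifest.json`;
`blinr.rician_bias_correct` removes the Rician floor when a reference
comparison calls for it).  `blinr fit-adc --vol b0=… --vol b500=… --vol
b1000=… --out adc.nii.gz` then turns any such series into an ADC map in
mm²·s⁻¹.

The same pipeline is scriptable from Python (`blinr.fit`,
`blinr.denoise_series`, `blinr.run_sweep`); see the docstrings and
`docs/methods.md` for the model details and parameter guidance.

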