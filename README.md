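# mritool

Speckle simulation, homomorphic Bayesian MAP denoising, restoration and
evaluation for MR images — plus the two-group clinical statistics that
typically accompany an imaging study.

## The problem

MR images degraded by multiplicative speckle are hard to read and hard to
segment. `mritool` models the corruption as

```
y = l · i + a
```

where `l` is the noise-free image, `i` is i.i.d. multiplicative speckle
whose amplitude follows a one-sided Rayleigh density with attenuation
parameter `d`,

```
r(t) = (t / d²) · exp(−t² / 2d²),   t ≥ 0,
```

and `a` is additive noise small enough to ignore. Taking logarithms turns
the multiplicative corruption into an additive one (`f = m + n` with
`f = log y`, `m = log l`, `n = log i`): the homomorphic domain in which the
denoiser operates.

Each pixel's denoised log value is the maximum-a-posteriori estimate

```
ẑ(y) = argmax_z [ log h_t(y − z) + log h_z(z) ]
```

with both the noise likelihood `h_t` and the signal prior `h_z` taken as
two-sided normalized Rayleigh densities (parameters `noise_d`, `prior_d`).
The maximization is numerical — coarse grid, fine grid, golden-section
refinement — and verified in the test suite against dense-grid search. Two
classical homomorphic steps wrap the per-pixel estimator: a radiometric
debias by the known log-mean of Rayleigh speckle (`log d + (log 2 − γ)/2`),
and a median background/detail split so that the zero-mode symmetric prior
acts on fluctuations rather than absolute log intensities. See
`docs/methods.md` for the full account.

Around the denoiser the package provides:

- **phantoms and noise** (`mritool.phantoms`, `mritool.noise`) — anatomy-like
  synthetic images, seeded Rayleigh speckle fields, log-domain separation,
  and the moment estimator `d̂ = √(mean t² / 2)`;
- **restoration** (`mritool.restore`) — the weighted low-resolution
  observation model `A[m,n] = Σ_s Q[m,n,s]·X[s] + l[m,n]` with least-squares
  inversion, enhancement by descent on `‖b − j⊛g‖²`, between-class-variance
  (Otsu) threshold segmentation, and central-difference edge detection;
- **metrics** (`mritool.metrics`) — SNR in dB and Gaussian-window SSIM
  against a clean reference;
- **clinical statistics** (`mritool.clinical`) — pooled/Welch t-tests from
  mean ± SD summaries, Pearson χ² and Fisher exact tests on 2×2 incidence
  tables, and direction-aware UPDRS / MoCA / MMSE score interpretation;
- **I/O and CLI** (`mritool.io`, `mritool.cli`) — PNG/TIFF/NIfTI and
  CSV/TSV readers and writers and an umbrella `mritool` command
  (`simulate`, `denoise`, `evaluate`, `segment`, `reconstruct`, `stats`,
  `pipeline`) with JSON reports throughout.

## Worked example

```python
import mritool as mt

clean = mt.make_phantom((64, 64), "shepp_like", seed=2)
noisy = mt.apply_speckle(clean, mt.SpeckleParams(d=0.3, additive_sigma=1e-3, seed=52))
report = mt.denoise_image(noisy, mt.MapConfig(speckle_scale=0.3))

print(report.summary())
print(f"SNR  before {mt.snr(clean, noisy):.2f} dB   after {mt.snr(clean, report.denoised):.2f} dB")
print(f"SSIM before {mt.ssim(clean, noisy):.3f}     after {mt.ssim(clean, report.denoised):.3f}")
```

prints

```
MAP speckle denoising report
  image shape          : (64, 64)
  noise_d used         : 0.343045
  prior_d used         : 0.25175
  speckle scale debias : 0.3
  pixels floored       : 0
  objective evaluations: 4362240
SNR  before 3.73 dB   after 9.15 dB
SSIM before 0.224     after 0.375
```

The report records the noise and prior Rayleigh parameters the estimator
actually used (both estimated from the image here), how many pixels the
positivity floor touched, and how much work the per-pixel maximization did.
SNR and SSIM are measured against the clean phantom, so the before/after
pair quantifies exactly what the denoiser gained: +5.4 dB and +0.15 SSIM on
this image.

The same run from the shell:

```
mritool simulate --kind shepp_like --d 0.3 --seed 2 --out-clean clean.png --out-noisy noisy.png
mritool denoise  --in noisy.png --out denoised.png --speckle-scale 0.3
mritool evaluate --ref clean.png --test denoised.png
```

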