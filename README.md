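# caldenoise

Model-blind spatiotemporal denoising of two-photon Ca²⁺ imaging movies.

Two-photon Ca²⁺ imaging records neuronal activity as movies, but photon
counts are low: frames are corrupted by signal-dependent shot (Poisson)
noise plus Gaussian read noise, `m = t + ns_p(t) + ns_g`. `caldenoise`
restores such movies with a 20-layer residual convolutional network that
takes three consecutive frames as channels and predicts the noise residual
of the middle frame; the clean estimate is `mean(stack − residual)` over the
three output channels. Training is two-stage:

1. **Supervised**: noisy stacks synthesized from a frame-averaged reference
   (Poisson magnitude 1, Gaussian SD ~ U(0, 0.05)) against the clean
   reference, L2 residual loss, Adam at constant lr 1e−4.
2. **Noise-to-noise fine-tuning**: raw 4-frame windows only — frames 1–3 as
   input, frame 4 as target — adapting the network to the real (unknown)
   noise without any clean data.

The package also provides the synthetic-movie simulator (soma-like blobs
with exponential-rise/decay Ca²⁺ transients, optional nonuniform motion),
and the evaluation suite: PSNR, SSIM, ROI traces with
Δf/f = (f − f₀)/f₀ (f₀ = 25th percentile), and the transient
SNR = (Peak − mean(Baseline)) / SD(Baseline) with a 75 ms peak window and a
2 s baseline window.

It is intended for imaging labs and methods developers who want a
reproducible, framework-free (pure numpy/scipy) reference implementation of
the method plus a simulator to characterize it.

## Worked example

Run the bundled desk-scale study (128×128 px, 40 Hz, 10 cells, 300 frames;
two-stage training of the 20-layer network on one CPU, ~8 min):

```python
from caldenoise import RunConfig
from caldenoise.pipeline import run_pipeline

summary = run_pipeline(RunConfig().with_seed(101))
print({k: round(v, 4) for k, v in summary.items() if isinstance(v, float)})
```

Output (seed 101):

```
{'psnr_noisy_mean': 32.3662, 'psnr_noisy_sd': 4.5936,
 'ssim_noisy_mean': 0.6314, 'ssim_noisy_sd': 0.1979,
 'psnr_denoised_mean': 42.1738, 'psnr_denoised_sd': 2.065,
 'ssim_denoised_mean': 0.9641, 'ssim_denoised_sd': 0.0169,
 'finetune_noise_floor': 0.0009}
```

Reading this: on 40 held-out frames the raw corrupted movie scores
PSNR 32.4 dB / SSIM 0.63 against the clean ground truth; after two-stage
training the denoised frames reach PSNR 42.2 dB / SSIM 0.96 — noise is
almost entirely removed while cell structure is preserved. The fine-tuning
loss (1.15e−3 at its last epoch) plateaus just above the computed
noise-variance floor of its noisy targets (8.7e−4), the expected signature
of noise-to-noise learning: the loss stays large even though the network
improves.

The same workflow is scriptable from the shell:

```sh
caldenoise pipeline --seed 101 --out runs/demo
caldenoise simulate --seed 3 --frames 200 --out movie.tif
caldenoise denoise  --weights runs/demo/model.npz --movie movie.tif --out clean.tif
caldenoise evaluate --ref ref.tif --test clean.tif --report report.csv
```

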