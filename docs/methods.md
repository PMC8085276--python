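# Methods

## Problem and approach

Two-photon Ca²⁺ imaging movies are corrupted by signal-dependent shot noise
(few photons reach the detector) and additive Gaussian read noise. This
package restores such movies with a residual spatiotemporal convolutional
network trained in two stages:

1. **Supervised stage.** A clean-ish reference of a fixed field of view is
   obtained by averaging many frames (default 100). The reference is
   corrupted synthetically with the Poisson+Gaussian model; three
   independently corrupted copies are stacked as a 3-channel input and the
   reference (replicated into 3 channels) is the target.
2. **Model-blind noise-to-noise stage.** Raw movie frames are treated as
   independent noisy observations of the same underlying scene. The movie is
   partitioned into non-overlapping 4-frame windows; frames 1–3 form the
   input stack and frame 4 (replicated) the target. No clean data is used;
   the pretrained weights are loaded and the whole network is retrained with
   nothing frozen.

At inference the network sees the stack (n−1, n, n+1), predicts the
*residual noise* per channel, and the clean estimate of frame n is
`mean(stack − residual)` over the three output channels, clipped to [0, 1].
Edge frames use replicate padding of the frame sequence so the output frame
count equals the input's.

## Noise model

A ground-truth frame `t` (intensities in [0, 1]) is corrupted as

    m = t + a · (Poisson(B·t)/B − t) + N(0, σ²)

with photon budget `B` (expected photons at intensity 1; default 1000),
shot-noise magnitude `a` (default 1 = physical shot noise at budget B;
0 = exact identity) and Gaussian SD `σ`. For training data σ is drawn
uniformly from (0, 0.05), once per 3-frame sequence (shared by its frames);
for simulated movies σ is drawn per frame. Corrupted frames are **not**
clipped — the additive-noise statistics stay exact (mean `t`, variance
`a²·t/B + σ²`) — and a separate clip utility exists for export. Separating
shape (B) from strength (a) keeps the magnitude parameter dimensionless and
makes zero magnitude an identity.

## Synthetic scenes

Cells are isotropic Gaussian-profile blobs (σ_blob = radius/2) truncated at
2σ_blob; the truncation disc doubles as the cell's ROI mask. Cells are
placed by rejection sampling with a minimum separation so profiles never
overlap, which makes the returned per-cell traces *exactly* the mask-mean of
the rendered movie. Each cell's brightness is
`soma_brightness · (1 + Σ transients)` over a flat background; transients
have the double-exponential kernel `(1 − e^{−t/τ_r})·e^{−t/τ_d}` (unit peak,
defaults τ_r = 0.05 s, τ_d = 0.5 s — standard Ca²⁺-indicator phenomenology)
with Poisson-process onsets (default 0.25 Hz per cell) and uniform
amplitudes in (0.2, 0.8). Activity is capped so peak blob intensity never
exceeds 1 (indicator saturation), avoiding a clip discontinuity.

The simulator does **not** model optical PSF, scanning artifacts, bleaching,
axial blur, neuropil, or dendrite morphology. Passing tests on these movies
demonstrate the pipeline's statistical behavior under the stated noise
model, not performance on the full complexity of in-vivo recordings.

Motion artifacts are simulated as per-frame rigid shifts (bilinear
interpolation) or smooth nonuniform displacement fields (coarse random grid,
default 4×4, cubic-upsampled; pull convention; out-of-frame regions filled
with the background level).

## Network and training

The network has 20 convolutional layers, 3×3×c kernels (c = 3 channels),
128 filters in the first layer and 64 in the rest, a final 3-channel layer,
leaky ReLU (slope 0.1) after every layer except the last, same (zero)
padding, and no normalization layers — 706,883 parameters. Weights use
fan-in variance scaling with the leaky-ReLU gain; biases start at zero.
The final denoised frame averages the three output channels (the target is a
3-fold replication, so the channels are symmetric); taking the center
channel instead is a near-equivalent alternative.

The loss is the mean squared error between the predicted residual and the
desired residual `input − target`. Optimization is Adam (β₁ = 0.9,
β₂ = 0.999, ε = 1e−8) at a constant learning rate 1e−4 — no schedule — for
50 initial + 10 fine-tune epochs at full scale. Best-validation weights are
kept (deterministic seeded 90/10 split). Everything is bit-reproducible
under a fixed seed. The convolution engine is written directly on numpy
(im2col + BLAS GEMM, analytic backward passes verified against finite
differences), so training and inference run on a single CPU with no
deep-learning framework.

Because stage-2 targets are noisy, the stage-2 loss is bounded below by the
mean target-noise variance `mean(a²·t/B) + σ²`; it is expected to plateau
near that floor rather than decrease substantially — the signature of
noise-to-noise learning.

## Evaluation

* **PSNR** `10·log10(range²/MSE)` in dB; identical images give `inf`.
* **SSIM** single-scale, 11×11 Gaussian window (σ = 1.5), K₁ = 0.01,
  K₂ = 0.03, population weighting, averaged where the window fits entirely
  inside the image. (Cross-checked against scikit-image in the test suite.)
* **Traces** f(t) = ROI-mean per frame; baseline f₀ = 25th percentile of
  the trace (linear interpolation between order statistics, stated
  explicitly so tests are exact); Δf/f = (f − f₀)/f₀, requiring f₀ > 0.
* **Transient SNR** = (Peak − mean(Baseline)) / SD(Baseline) on Δf/f, with
  Peak the mean over a 75 ms window centered on the peak index and Baseline
  the 2 s window ending immediately before the peak window (adjacent
  placement; window lengths in frames via `max(1, round(s·rate))` — 3 and 80
  frames at 40 Hz). SD is the sample standard deviation (N−1). Zero baseline
  SD or non-positive f₀ raise a degenerate-baseline error. Peak indices are
  caller-supplied; an argmax helper is provided.

## Desk-scale study

The bundled study (defaults of `RunConfig`; used by `scripts/acceptance.py`
and the claim-level tests) runs the whole procedure at a scale chosen for a
single CPU with the numpy engine:

* 128×128 px, 40 Hz, 10 cells, 300 frames: frames 0–99 averaged into the
  reference, 100–259 fine-tuning (40 noise-to-noise windows), 260–299 held
  out for evaluation.
* Corruption: Poisson magnitude 1 at B = 1000, per-frame σ ~ U(0, 0.05).
* Supervised set: 40 full-frame pairs × 8 random 24×24 crops = 320 patch
  pairs; noise-to-noise set: 40 windows × 8 crops = 320 patches.
* Training: the full 20-layer network, Adam lr 1e−4, batch 8, 15 initial +
  5 fine-tune epochs (~540 + 180 optimizer steps — comparable, after
  scaling, to the step budget the full-scale schedule implies).
* Evaluation: PSNR/SSIM of the denoised held-out frames against the clean
  per-frame ground truth, alongside the same metrics for the raw noisy
  frames.

Patch size (24 px) and batch size are free parameters of the scaled study —
neither is stated for the original full-scale procedure. The patch is
smaller than the network's 41×41 receptive field, which truncates the
longest-range context during training but leaves inference (full frames)
unaffected.

## Numerical choices and edge cases

* All network math in float32; metrics in float64.
* Percentile convention: numpy's linear interpolation.
* `corrupt` rejects negative intensities; zero magnitude and zero σ is an
  exact identity.
* `average_reference` of one frame is that frame; empty sequences are
  rejected.
* Checkpoints round-trip config + weights + provenance bit-exactly.
* Movie TIFFs are 16-bit with JSON scaling metadata; quantization error is
  bounded by 1/65535.

## Known limitations

* The synthetic scenes are far simpler than in-vivo data (no neuropil,
  vessels, z-drift, bleaching); absolute quality numbers on real recordings
  will differ.
* The engine is single-threaded numpy: full-scale (500×500, 50-epoch)
  training is possible but slow; the desk-scale defaults are the supported
  configuration.
* No-reference (blind) image-quality scoring is out of scope (requires an
  externally trained natural-scene-statistics model); report schemas keep an
  optional column for it.
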