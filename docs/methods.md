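# Methods

## Problem setting

Multi-arterial gadoxetate-enhanced liver MRI acquires one pre-contrast
and six arterial phases of the same slice within a breath-hold. When the
breath-hold fails, the object moves between phase-encode line
acquisitions and the reconstructed magnitude image shows ghosting along
the phase-encode axis. This package simulates that corruption in
k-space, trains a residual convolutional filter to extract the artifact
component from the 7-channel phase stack, and evaluates the filter with
full-reference quality metrics on synthetic phantoms.

The unit of data throughout is the `PhaseStack`: a real, non-negative
array of shape (rows, cols, 7) — one axial slice at seven temporal
phases — plus an `AcquisitionGeometry` (matrix size, field of view,
phase-encode axis, readout duration, line ordering).

## Motion model

Rigid in-plane displacement d(t) along the phase-encode direction at
acquisition time t multiplies k-space line k_y by exp(i·φ(k_y)) (Fourier
shift theorem). For sinusoidal breathing,

    φ(k_y) = 0                                  |k_y| < k_y0
    φ(k_y) = 2π·k_y·Δ_px·sin(α·t(k_y) + β)/N    otherwise

* **Δ_px** — displacement amplitude in pixels. The physical amplitude is
  specified in cm (range 0.0–2.6 cm, the realistic respiratory
  envelope) and converted as Δ_px = Δ_cm·10/(fov_mm/N), so the same
  physical motion means the same fraction of the field of view at any
  matrix size.
* **α** — respiratory phase advance per acquired line:
  α = 2π·f·T_readout/N with f ∈ [0.2, 0.7] Hz and T_readout ≈ 4 s (the
  temporal resolution of one dynamic phase). Under *linear* ordering the
  acquisition-time index t(k_y) is k_y itself; under *centric* ordering
  (the default, matching centre-out clinical acquisitions) it is the
  centre-out rank of k_y, DC first, positive line before negative at
  equal |k_y|.
* **β** — sine phase offset, drawn uniformly from [−π, π]. It is exposed
  independently of the centric time origin.
* **k_y0 = 20 px** — protected half-width of the k-space centre. Low
  frequencies carry the contrast information; leaving them untouched
  mirrors how the corruption model preserves clinical contrast.

The irregular-breathing mode draws the number M of corrupted lines
uniformly from {0, …, N − 2·k_y0}, picks M lines outside the protected
band without replacement, and gives each an independent displacement
d ~ U[−Δ_px, +Δ_px] (φ = 2π·k_y·d/N). All draws are seeded.

Corruption of an image is: real 2-D FFT → per-line phase multiplication
→ inverse FFT → magnitude. It is *phase-only*: per-line k-space
magnitudes and total image energy are conserved to floating-point
precision, centre-band coefficients bit-exactly. Inputs are treated as
real magnitude images (the training data of the clinical workflow are
DICOM-derived magnitudes, not raw complex data). Signed k_y uses the
centred convention k_y = index − N//2, i.e. an fftshift-style layout
with DC at N//2.

Each of the 7 phases is corrupted independently (or left clean —
`corrupt_stack` accepts `None` per phase); sharing one realisation
across phases is possible by passing identical parameters.

## Phantoms

Clean stacks are superpositions of randomly placed soft-edged ellipses
(8–15 per slice in the benchmark), each with a piecewise-linear
per-phase enhancement multiplier (spread ±15% by default) — anatomy is
identical across phases, only intensities change, so the inter-phase
redundancy the filter exploits is present. A static multiplicative
texture field (Gaussian-correlated noise, 3 px correlation length, ±35%
amplitude) supplies the high-spatial-frequency content of abdominal
anatomy; without it, almost all phantom energy falls inside the
protected centre band and simulated motion barely degrades the image
(corrupted PSNR ≈ 40 dB), which is unrealistically benign. With texture,
corrupted PSNR sits around 28–33 dB over the displacement range —
artifacts that are clearly visible but leave anatomy recognisable. An
optional focal lesion is a hard-edged disk with its own 7-point
enhancement curve (arterial-like rise and washout in the benchmark) and
additive amplitude, so lesion contrast is exactly controllable.

Intensities lie in [0, 1]; the generator is bit-deterministic given its
seed. What the phantoms do *not* model: pharmacokinetic enhancement
curves, organ-specific shapes, coil sensitivity profiles, receiver
noise, and through-plane anatomy. Results on phantoms therefore
demonstrate that the pipeline removes the *simulated* artifact class —
they do not certify performance on patient data.

## Patch pipeline

Training pairs are sliding-window crops (96×96×7, stride 48 = 50%
overlap by default; the stride is a free choice) from the corrupted
stack (input) and from corrupted − clean (target residual). Both are
divided by the global maximum of the corrupted stack; the scale is
stored per pair, making the normalisation exactly invertible. Patches
are float32; the pair archive is a single HDF5 file (`noisy`,
`residual`, `scale`, `origin`).

## Network and training

Seven layers of same-padding 3×3 convolutions; layers 1–6 are followed
by batch normalisation and ReLU, the last layer is a plain convolution
(the artifact residual is signed, so a ReLU output would be wrong —
which is also why the printed "each layer has BN+ReLU" cannot apply to
the output layer of a residual regressor). The first and last layers
have 7 filters, the hidden layers 64; 156,949 learnable parameters.
Whether the first layer should instead carry 64 filters is ambiguous;
both are supported (`allow_nonstandard=True`), the default follows the
7-filter reading. The network is fully convolutional: a filter trained
on 96×96 patches runs on any slice size (e.g. 320×192) without
cropping; whole-image and cropped predictions agree away from a 7 px
boundary margin.

Because no deep-learning framework is part of the supported
environment, the convolutions, batch-norm, loss and optimisers are
implemented directly in numpy (`marc.nn`): convolution as an im2col +
BLAS matmul with persistent scratch buffers (large repeated allocations
dominate run time on a single-core machine), analytic gradients
verified against finite differences to ~1e-6, Adam with bias
correction. Everything is float32 by default and bit-reproducible given
a seed on a fixed platform.

Training minimises MSE between predicted and true residual patches
(residual learning). Choices the source protocol leaves open, and how
they were fixed:

* **Optimiser** Adam, lr 1e-3. A pilot grid (1e-3/3e-3/1e-2, one epoch,
  ~500 pairs) showed larger rates gave worse validation loss.
* **Last layer zero-initialised**, so training starts from the identity
  filter (predicted residual 0). With random output-layer
  initialisation the network first has to unlearn a large random
  residual; in pilots it had not even recovered the predict-zero
  baseline within 5 epochs, while zero-init improves from step one.
* **Batch size 2** rather than a conventional 32: per-sample cost is
  nearly flat in batch size on one CPU, so smaller batches buy
  proportionally more optimiser steps per minute, which is what
  convergence is limited by at desk scale. A batch-2/batch-4 pilot at
  equal wall-clock confirmed the smaller batch reached lower validation
  loss.
* **Validation fraction 0.1**, fixed seeded split and shuffling.

`denoise` normalises a stack by its own maximum, predicts the residual,
and returns input − scale·residual (exact algebraic inversion of the
training normalisation; an oracle residual recovers the clean stack to
float32 rounding). Outputs may contain small negative values; clipping
at zero is optional for display.

## Desk-scale benchmark

`marc.benchmark.run_desk_benchmark` is the package's end-to-end
experiment, scaled to a single CPU:

* 125 phantom slices (256×256×7) → 16 patch positions each → 2,000
  pairs (the clinical-scale reference uses 14,190 patches).
* Per-phase corruption with probability 0.8, Δ ~ U(0, 2.6) cm,
  f ~ U(0.2, 0.7) Hz, β ~ U(−π, π), periodic/random 50:50, k_y0 = 20 px.
  The pre-contrast phase is always left clean, in training and
  evaluation alike: transient severe motion is contrast-induced
  dyspnoea, so the phase acquired before injection is artifact-free.
* Training: 2 epochs, batch 2, Adam lr 1e-3 (1,800 steps, ~12 min of
  CPU time).
* Evaluation: 10 held-out stacks corrupted from the same distribution.
  PSNR is computed per stack, with the squared error pooled over that
  stack's corrupted phases, then averaged over stacks — the stack is
  the evaluation unit; a per-channel average would instead be dominated
  by channels that happened to draw Δ ≈ 0, whose near-infinite baseline
  PSNR collapses under any filter-induced change. Per-phase SSIM and
  mean absolute errors are reported alongside, plus the mean absolute
  change the filter introduces on clean phases versus the mean absolute
  error it removes on corrupted ones (anatomy preservation).

All randomness derives from one seed. `scripts/acceptance.py` runs this
benchmark plus the simulator invariant checks and writes the measured
numbers as JSON.

## Numerical notes and degenerate inputs

* Zero-amplitude motion and all-`None` phase lists return inputs
  bit-identically; all-zero stacks pass through patching (unit scale)
  and denoising (returned unchanged) without division by zero.
* PSNR uses the reference maximum as peak and returns +inf for
  identical images; SSIM uses the standard Gaussian 7×7 window with
  K1 = 0.01, K2 = 0.03 and the reference dynamic range.
* Even matrix sizes place DC at index N/2; the signed index range
  [−N/2, N/2) is asymmetric, so for N = 64 and k_y0 = 20 there are 25
  eligible lines but at most N − 2·k_y0 = 24 ever corrupted.
* Training aborts with a diagnostic on non-finite loss rather than
  returning silently broken weights.

## Known limitations

* Rigid, in-plane, phase-encode-direction motion only: no through-plane
  motion, non-rigid deformation, view-sharing or parallel-imaging
  (sub-sampling) artifact mechanisms.
* The filter is trained and evaluated on the same synthetic artifact
  and phantom distribution; transfer to patient data is out of scope
  here and would require clinical training data.
* Reader-score emulation is deliberately not attempted: there is no
  principled mapping from PSNR/SSIM to a 4-point ordinal artifact
  score.
* At desk scale the network is under-trained relative to a GPU-scale
  run; the benchmark demonstrates that the pipeline learns and improves
  held-out quality, not the ceiling of the architecture.
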