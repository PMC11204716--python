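# Methods

This note records the scientific model behind `xfctdn`, the choices made
where the design was genuinely open, and what the desk-scale experiments
do and do not demonstrate.

## Problem setting

X-ray fluorescence computed tomography (XFCT) images the distribution of
a high-Z contrast agent (here gadolinium, K-alpha ≈ 43 keV) by counting
characteristic fluorescence photons. With benchtop polychromatic sources
the dominant noise source is Compton-scattered primary photons landing in
the XRF energy window, and acceptable sensitivity currently requires high
radiation dose. The package studies the dose/quality trade-off: it
simulates low-dose acquisitions of a known phantom, trains a Swin-Conv
UNet to map low-dose reconstructions back to their full-dose references,
and benchmarks it against classical denoisers with PSNR and SSIM.

## Synthetic phantom model

A reconstructed XRF slice is modeled directly in image space (no
tomographic forward model) as an *expected photon count* per pixel:

```
lambda(p) = compton_level
          + water_level     * 1[p in hexagon]
          + signal_gain * c_t * 1[p in tube t]
```

blurred by an isotropic Gaussian PSF (`psf_sigma`, default 1.5 px). The
geometry mirrors the benchtop study object: a flat-top regular hexagonal
water container of 50 mm maximum diameter (pixel-center membership, no
sub-pixel anti-aliasing) holding 8 mm circular tube inserts with Gd
weight fractions in {0, 0.031, 0.1, 0.2, 0.31} wt%. Geometry scales with
the image (hexagon circumradius 0.45·min(H, W)).

Default intensity levels (counts/pixel at the reference 0.5 keV bin and
unit exposure): `compton_level = 5`, `water_level = 3`,
`signal_gain = 10 000` (so the strongest insert, 0.31 wt%, adds ≈ 31
counts/pixel on an ≈ 8-count background). These place the strongest
tube at roughly 4:1 signal-to-background and leave the finest energy bin
(10× fewer counts) severely photon-starved, which is the regime the
method is meant for. What the generator does **not** emulate: detector
response and pinhole geometry, attenuation, sparse-view reconstruction
streaks, spectral peak shapes (the energy-bin width acts purely as a
multiplicative expected-count factor `bin/0.5`), or anatomical
variability. Consequently, passing tests show that the pipeline learns
and measures what it claims on count-statistics-faithful images — not
that the trained weights transfer to real benchtop data.

## Dose degradation

"Noise level L%" denotes removal of L% of the photons (0% = full dose).
The full-dose image is a per-pixel Poisson draw of `lambda`; dose
reduction is per-pixel binomial thinning with keep fraction `1 − L/100`.
Thinning a Poisson field is again Poisson with mean scaled by the keep
fraction, so this is the physically faithful low-dose simulation (rather
than additive Gaussian noise). The thinning-composition and
variance/mean properties are asserted in the test suite.

## Normalization

Networks consume images in [0, 1]. The default is fixed-range
normalization: counts divided by `cmax`, the 99.5th percentile of the
full-dose count images of the *training* phantoms, computed per bin
width (bin widths change expected counts by 10×) and shared across dose
levels within a bin width. Sharing `cmax` across dose levels means dose
reduction visibly darkens the input — the network sees, and must invert,
the full degradation including the global count deficit.

A consequence worth stating explicitly: under this convention the MSE of
a 75%-reduction input against its full-dose target is dominated by the
0.75× brightness bias, which no brightness-preserving classical denoiser
(NLM, BM3D) can remove; their PSNR then sits at or slightly below the
identity floor while the trained network, which learns the gain, clears
it by several dB. For exposure-matched comparisons
`build_dataset(..., dose_compensate=True)` divides the noisy image by
its keep fraction; in that mode the classical baselines beat the
identity floor in the noise-dominated bins, and the sanity-ordering test
asserts exactly that. `per_image_max` normalization is available behind
a flag.

## Dataset assembly and split

For each phantom × bin width one full-dose image is drawn; each noise
level thins it. The clean target is the normalized full-dose image of
the same phantom/bin. Augmentation is exactly the original plus 90/180/
270° rotations (4×), applied after pairing so both members rotate
together. The 20% hold-out is a seeded *phantom-level* split shared
across all (bin, level) categories: each category then holds exactly
`round(0.2·n_phantoms)·4` test pairs, and neither rotated copies nor the
same phantom geometry ever straddle the split. All randomness derives
from one master seed through keyed `SeedSequence` children
(`child_rng(seed, stage, item, ...)`), so any single stage is
independently reproducible and dataset construction is a pure function
of (specs, grids, seed).

## Network

The denoiser is a 4-scale UNet of swin-conv (SC) blocks:

```
x1, x2 = split(conv1x1(x));  z = conv1x1(concat(SwinT(x1), RConv(x2))) + x
```

with 2×2 stride-2 convolutions for downscaling, 2×2 transposed
convolutions plus additive skips for upscaling, 3×3 head/tail
convolutions, channels 64/128/256/512 and four SC blocks per scale
(`full` preset). The Swin branch uses plain windowed multi-head
attention (window 8, head dim 32, MLP ratio 4) with cyclic shifts
alternating 0, w/2 within each block run and masked attention across
wrap seams; learned relative-position bias is omitted for a minimal
parameterization. Arbitrary input sizes are reflect-padded to the least
multiple of 8·window and cropped back.

Numerical choices: float64 throughout (the package's autodiff engine is
NumPy-based); truncated-normal init (σ = 0.02, clipped at ±2σ) for
attention/MLP weights, Kaiming-normal for convolutions; and the fusion
1×1 convolution of every SC block is **zero-initialized** so each block
starts as the identity — without this the 24-block residual stack
amplifies activations by ~50× at init and desk-scale training diverges.
A `tiny` preset (16/32/64/128 channels, one SC block per scale, window
4, ≈ 0.35 M parameters) is the desk-scale configuration used by the
tests and the acceptance script.

## Training protocol

Adam, learning rate `1e-4 · 0.9^epoch` (per-epoch decay; a literal
per-iteration decay of 0.9 would annihilate the step size within one
epoch), 40 epochs and batch size 2 at full scale. The multi-level
protocol is: train at the 25% noise level, then fine-tune per level from
that checkpoint (`--finetune-from`); a `--joint` flag trains one model
on all levels instead. Validation (10% carved from the training split;
the 20% hold-out stays untouched) selects the best-PSNR epoch, whose
weights are checkpointed. Fine-tuning never re-initializes: the
parameter hash before the first step equals the checkpoint hash, and a
test asserts it.

The compound loss is

```
L = L1 + alpha·(1 − SSIM) + beta·mean(W ⊙ |pred − target|),
```

`alpha = 0.5`, `beta = 1`, where W is the target's gradient-magnitude
map normalized to mean 1 (uniform for constant targets). It is this
package's concrete interpretation of a shape-aware weighting — edges of
the Gd inserts, where clinical information lives, are weighted above
flat water/background — not a replication of any published formula.
`alpha = beta = 0` reduces it to plain L1. The SSIM term reuses the same
Gaussian-window formula as the reported metric, evaluated
differentiably.

## Metrics

PSNR = `10·log10(range²/MSE)` (identical images report `inf`; infinite
cells are excluded from table means and counted in a footnote). SSIM
uses the standard local-statistics form with an 11×11 Gaussian window
(σ = 1.5), K1 = 0.01, K2 = 0.03, data range 1.0 on normalized images,
averaged over fully interior windows; all constants are recorded in the
report metadata. Both are verified against brute-force per-window
oracles to ≤ 1e-9 dB / ≤ 1e-6.

## Baselines

* **NLM**: exhaustively verified vectorized implementation; weights
  `exp(−SSD/h²)` on raw (2p+1)² patches, reflect borders; defaults
  patch radius 2, search radius 7, `h = sqrt(2·n_patch)·sigma_hat` with
  `sigma_hat` the median-absolute-deviation estimate from the finest
  Haar HH band.
* **BM3D (simplified)**: two-stage collaborative filtering — block
  matching by L2 distance, 2-D DCT per block + 1-D Haar across the
  stack, hard threshold at 2.7σ, aggregation weighted by 1/(1+kept
  coefficients), optional Wiener second stage using the first-stage
  pilot. It is a native simplified variant, not a replication of
  reference BM3D binaries; external implementations (including a
  volumetric BM4D) can be plugged into the denoiser registry for strict
  comparisons.
* **DnCNN**: depth-17, 64-channel residual CNN predicting the noise
  (conv+ReLU, 15× conv+BatchNorm+ReLU, conv), trained with the shared
  pipeline rather than its original Gaussian-σ protocol.

## Problem sizes used

The test suite and acceptance script run the `tiny` preset on 64×64
phantoms: the desk-scale learning experiment uses 40 phantoms (32
train / 8 held out; 128/32 pairs after 4× rotation) at the 75%
reduction level, 0.5 keV bin, 5 epochs — chosen so a complete
train-and-evaluate cycle is a minutes-scale computation while still
exercising every pipeline stage. Typical outcome: held-out PSNR rises
from ≈ 14 dB (noisy input) to ≈ 21.5 dB, with NLM at ≈ 13.7 dB on the
same pairs. These numbers characterize the synthetic desk-scale
conditions only; they are not comparable to benchtop-data results
obtained with GPU-scale training.

## Known limitations

* The autodiff engine implements exactly the operator set the networks
  need; it is single-device, float64, and makes no attempt at memory
  efficiency beyond what the desk-scale problems require.
* Phantom realism is limited as listed above; in particular no
  reconstruction artifacts are simulated, so the noise is spatially
  white, which flatters patch-based methods relative to real sparse-view
  data.
* The BM3D variant is simplified; its absolute PSNR is not comparable to
  reference implementations.
* The `full` preset (≈ 17.9 M parameters) trains only at time scales
  beyond a desk run; it is exercised for construction and parameter
  accounting, not trained in the test suite.
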