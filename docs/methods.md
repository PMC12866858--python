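# Methods

## Model

`msifuse` treats super-resolution fusion as a per-pair regression: a residual
convolutional network f(X; θ) maps the registered H×W×3 microscopy image X to
a single-channel H×W image y, and θ is fitted for this one pair only. The
approach is deliberately non-generalizing — MSI datasets are scarce and
stainings heterogeneous, so no transferable prior is assumed. The target side
is the native h×w ion image enlarged bilinearly by the integer magnification
m = H/h; the morphology side is X itself, compared through a fixed edge
filter.

Architecture: one initialization block (3×3 convolution 3→64, ReLU) and two
residual blocks. A residual block with channels c_in→c_out applies two 3×3
convolutions (c_in→c_out, ReLU, c_out→c_out) and adds a parallel 1×1
convolution of the block input; block 1 (64→32) is ReLU-activated after the
sum, block 2 (32→1) is left linear. All convolutions are same-size with
replicate padding. Total: 31 916 trainable parameters; the 3-layer CNN
baseline (3→64→32→1, no skips) has 20 545.

Two points here were genuinely open and are this package's decisions:

* **Final activation.** A terminal ReLU would clamp all negative pre-outputs
  to zero at initialization and stall training on [0,1]-normalized targets,
  so the output head is linear and clipping to [0,1] happens only on export.
* **Within-block widths.** Only the block-boundary channel counts are
  dictated (64, 32, 1); the hidden width inside each block is set equal to
  the block's output width, the smallest consistent choice.

## Losses

With N = M = H·W,

* L_MSE = mean((y − ŷ)²), ŷ the normalized bilinear enlargement of the ion
  image;
* L_edge = mean((K⊛y − K⊛lum(X))²), K a designated 3×3 kernel applied with
  replicate padding, lum the Rec. 601 luminance (0.299 R + 0.587 G +
  0.114 B);
* L = w1·L_MSE + w2·L_edge, defaults w1 = w2 = 1.

Choices and rationale:

* **K defaults to the 4-neighbor Laplacian** [[0,−1,0],[−1,4,−1],[0,−1,0]] —
  the canonical single-kernel edge extractor, keeping the edge loss a single
  convolution. Laplacian-8 and Sobel variants are selectable; kernels are
  applied as written (cross-correlation), which matters only for the
  asymmetric Sobel options.
* **Replicate padding** everywhere: zero padding would manufacture a dark
  frame whose strong artificial edges dominate L_edge at the borders.
* **Luminance, not per-channel edges**, compares the 1-channel output to the
  3-channel microscopy; some reduction is unavoidable and luminance is the
  least arbitrary.
* **M counts all H·W same-padded pixels** rather than valid-convolution
  pixels; the difference is a border-band scale factor that the tests pin.
* **Normalization.** Both modalities are min-max normalized to [0,1] so the
  two loss terms share a scale (their raw magnitudes differ by orders of
  magnitude). The ion image is normalized *after* interpolation so the [0,1]
  span is exact; whether and how the original workflow normalized
  intensities before the MSE term is unstated, and this per-image min-max is
  the package's own convention. Original-unit back-scaling bounds are
  retained by `minmax_normalize(..., return_bounds=True)`.

## Training and early stopping

Adam (β = 0.9/0.999, ε = 1e-8, lr 3e-4) on the full image, batch of one, cap
2000 epochs. The edge loss is the stopping signal and the checkpoint
criterion:

* every epoch whose L_edge is **not** strictly below the running minimum
  increments a cumulative counter (ties count as increases; the counter is
  never reset — the rule counts *total* increases, which is robust to
  noise-floor oscillation that would defeat a consecutive-epochs rule);
* training halts when the counter reaches the patience (default 5);
* the returned image comes from the epoch with minimal L_edge, restored from
  a parameter snapshot — never from the halting epoch. L_total keeps
  decreasing long after the output has begun to accumulate fuzzy artifacts,
  so minimal L_edge, not minimal L_total, selects the best checkpoint.

With weights (1, 0) the edge loss is still computed and recorded each epoch
but contributes no gradient; the test suite verifies the parameter
trajectory is bit-identical to a run that never forms the edge gradient.

The whole stack (convolutions, backward passes, Adam) runs on float64 numpy
arrays. At these sizes (≈32k parameters, one image) this is fast, dependency
-light, and deterministic on a given platform: a fixed seed reproduces
initialization, trace, and output bit-for-bit there, while cross-platform
runs may differ in floating-point reduction order. Gradient correctness is
pinned against central finite differences; the loss implementations against
scalar brute-force oracles.

## Synthetic phantom

The phantom generator emulates the structures that make plant tissue hard to
fuse: a seeded Voronoi tessellation plays the cell mosaic, 1–2 px darkened
boundaries play the cell walls, and concentric ring classes (vascular /
mesophyll / epidermis) give region-correlated ion abundance with mild
cell-to-cell jitter (10% by default). The low-resolution ion image is the
m×m block mean of the high-resolution truth (the laser spot integrates over
its footprint) plus Gaussian noise (sd 0.02 by default on abundances of
order 0.2–0.9), clipped at zero.

Default conditions used by tests and the acceptance script: 64×64 truth,
magnification 8 (so an 8×8 ion image), noise sd 0.02, ≤300 epochs, and the
default 40 Voronoi cells (unit tests on 32×32 grids use 10). These sizes keep a
full fusion run at ~30 s on one CPU while leaving the task non-trivial: an
8×8 ion image carries essentially no cell-level structure, so any cell-level
recovery must come through the microscopy channel.

What the phantom does *not* emulate: optics (PSF, chromatic effects), matrix
crystallization artifacts, registration error (pairs are perfectly aligned
by construction), Poisson counting statistics (noise is Gaussian), and the
full morphological diversity of real sections. Passing phantom tests
therefore demonstrates that the optimization, losses, and stopping rule do
what they claim under a known forward model — not that fused real images are
quantitatively accurate; on real data the fused image remains a model
prediction to be validated against the interpolated ion image and the
morphology.

## Numerical conventions

* Coordinates are 0-based (row, col), origin top-left, row-major; imzML
  1-based (x, y) indices are shifted on read.
* Ion extraction sums peak intensities within a ±5 ppm window by default.
* Bilinear enlargement uses half-pixel-center alignment with border
  clamping (the dialect of the common image-library linear resize), pinned
  against a scalar oracle and the scikit-image resize.
* Registration is a strict shape contract: microscopy shape must equal ion
  shape × magnification exactly, no silent crop or pad — exported
  registration images are a known source of off-by-a-crop mismatches, and
  these fail loudly.
* SSIM uses the canonical defaults: 11×11 Gaussian window (σ 1.5),
  C1 = (0.01 L)², C2 = (0.03 L)², L = 1, Gaussian-weighted moments, border
  crop of half a window; it matches the scikit-image reference to 1e-12.
  PSNR returns an infinity sentinel at zero MSE.
* Constant grids min-max normalize to all-zeros; degenerate by convention.
* Checkpoints carry parameters, optimizer state, the loss trace, a config
  hash, and a SHA-256 digest of the parameter bytes; loads refuse tampered
  files and mismatched configs, and a run can resume from any checkpoint,
  reproducing the uninterrupted trace exactly.

## Known limitations

* Per-platform, not cross-platform, bit determinism.
* The edge loss cannot detect the slowly accumulating fuzzy patterns of
  grossly over-trained runs; the early-stopping rule bounds, but does not
  eliminate, this failure mode.
* A pretrained-feature perceptual metric is exposed only as a hook
  (`metrics.register_feature_extractor`); no pretrained weights are shipped.
* Single ion per run; multi-ion joint fitting, learning-rate schedules, and
  adaptive loss balancing are out of scope.
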