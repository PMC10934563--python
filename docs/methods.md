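# Methods

## Problem setting

Intraoperative margin assessment with hyperspectral imaging faces a
resolution/speed trade-off: line-scanning cameras deliver high-resolution
reflectance hypercubes (~400–1000 nm, hundreds of bands) but are slow and
motion-sensitive; snapshot cameras are fast but spatially coarse.  `lumifuse`
implements an RGB-guided super-resolution scheme: a low-spatial/high-spectral
resolution hypercube (LR-HSI) and a high-resolution RGB image (HR-RGB) of the
same scene are fused and refined by a small convolutional network into a
high-resolution hypercube (HR-HSI).

A hypercube is an array `(Y, X, Z)` of dimensionless reflectance, nominally in
[0, 1]; `[row, col, band]` indexing, 0-based, half-open crop windows.

## Forward model (input simulation)

Because paired snapshot/RGB acquisitions of resection specimens are not
available, both network inputs are simulated from a high-resolution reference:

* **LR-HSI** — per-band Gaussian blur (truncated discrete kernel, default
  5×5, sd 10 px, reflect padding) followed by bilinear downsampling (default
  factor 4).  Blur precedes decimation (standard anti-aliased decimation).
  All Z bands are kept: only spatial resolution is reduced.
* **HR-RGB** — the reference bands nearest 650, 532 and 473 nm (order R, G,
  B), full resolution, no blur.  Nearest-band mapping breaks ties toward the
  lower index.

Resampling uses the pixel-center convention `src = (dst + 0.5)·scale − 0.5`
with border clamping (both directions share it, so constant cubes are fixed
points and linear ramps resample exactly).

Four corruption injectors emulate common acquisition problems, applied to the
LR-HSI only (the color camera is assumed clean, e.g. polarizer-filtered):
extra blur at kernels 5–35; zero-mean uniform noise of a chosen variance
(half-width `sqrt(3·var)`) confined to a wavelength window (default
980–1000 nm, the long-wavelength sensitivity roll-off); dead pixels (whole
spectra set to exactly 0, drawn from the foreground when given as a rate);
and specular-saturation plateaus (>1, default 1.2) inside small squares,
confined to 675–705 nm.  Noise is never clipped so the requested variance is
exact; noisy bands may dip below zero, as calibrated reflectance spectra do.
Test-time blur *replaces* the LR-generation blur rather than compounding it.

## Reconstruction network

Band-replacement fusion first: the LR-HSI is bilinearly upsampled to the
HR-RGB's size and the bands nearest the RGB wavelengths are overwritten with
the HR-RGB channels.  This guarantees — independent of any weights — that
those three bands are bit-exact and every other band is the bit-exact
bilinear upsample.

The network is three 3×3 convolutions (stride 1, zero padding 1), all with
input and output width equal to the band count Z:

    u      = ReLU(conv_a(fused))        # fusion stage
    prelim = u + conv_b(u)              # spatial reconstruction (residual)
    final  = prelim + conv_c(prelim)    # spectral reconstruction (residual)

ReLU appears only after the fusion stage so outputs can reach values near 0.
The residual skips are a config flag (default on).  Design choices where the
architecture was genuinely open:

* **Channel width** `l = L = Z` in every stage — the minimal choice
  consistent with a Z-band output.
* **Residual stages** — standard for restoration refinements, and they give
  the exact identity `final = ReLU(conv_a(fused))` at zero B/C weights,
  which pins the stage wiring in tests.
* **Initialization** — `conv_a` starts at the channel identity (delta
  kernel) plus small uniform noise; the B/C branches start at zero
  (zero-init-residual practice).  The untrained network is then
  `ReLU(≈identity)` of the fused input, a sensible starting point that makes
  short CPU training budgets workable.  A plain Kaiming-uniform scheme is
  available (`init_weights(..., scheme="kaiming")`).

### Losses

* spatial — MSE between first-order spatial difference maps (adjacent-pixel
  differences along rows and columns, per band) of the **preliminary**
  output vs the reference; invariant to global intensity offsets.
* spectral — MSE between adjacent-band difference stacks of the **final**
  output vs the reference; invariant to per-pixel offsets.
* fused — plain MSE of the final output (our reading of the fusion loss;
  the difference form of the spatial term is likewise one of two defensible
  readings, and raw-intensity MSE remains available as `fused_loss`).

The total is their sum, back-propagated once per step — equivalent gradients
to optimizing the staged sum, with a single loop.  Forward and backward
passes are written directly in NumPy (float64, shift-and-matmul convolution);
analytic gradients are verified against central finite differences to
≤ 1e-4 relative error.

## Training protocol

* Patient-grouped 60/20/20 split: patients are shuffled by seed and assigned
  greedily to the split with the largest remaining image quota, so all
  images of a patient stay together and realized counts track the targets.
* One full image per Adam step (no patch batching), shuffled order per
  epoch, fixed seeds throughout; reruns are bit-identical single-threaded.
* Defaults mirror the full-scale protocol: 10,000 epochs, Adam, lr 1e-4.
  An optional step decay (`lr_decay_every`/`lr_decay_factor`) is off by
  default.
* Every `eval_interval` (default 10) epochs the model is scored on the
  validation set with background-masked PSNR and SAM.  Weights are
  checkpointed only when PSNR strictly improves **and** SAM strictly
  improves over the best so far (ties do not checkpoint); the run continues
  for the full budget and the last checkpoint is returned ("early stopping"
  as best-checkpoint selection).  An optional patience can truncate.

## Quality metrics

All metrics exclude black background pixels via a mask derived from the
*reference* cube (foreground = mean reflectance over bands > 0.02).  The
masked pixel count replaces the full pixel count in every denominator.

* RMSE over masked pixels × bands.
* PSNR per band: `10·log10(max(G_k)² / MSE_k)`, max and MSE over masked
  pixels; band mean excludes exactly-reproduced (+inf) bands and reports
  their count.
* ERGAS: `100·ratio·sqrt(mean_k (RMSE_k/μ_k)²)`; `ratio` defaults to 1 for
  same-resolution comparisons and is exposed for LR-vs-HR scoring
  (`1/down_factor`).
* SAM: mean per-pixel angle in degrees; zero-norm spectra are skipped and
  counted; the arccos argument is clamped to [−1, 1].

## Synthetic phantom cohort

The generator emulates the gross structure of specimen imagery: an
elliptical specimen (~50% fill, randomized axes/rotation) on an exactly-zero
background; 2–4 spatially smooth tissue regions (argmax of smoothed random
fields); per-class endmember spectra built from 2–4 positive Gaussian bumps
plus a linear baseline, rescaled into [0.1, 0.9] and resampled until all
pairwise spectral angles are ≥ 5°; a smooth multiplicative texture field
(default sd 0.05) within classes; optional Gaussian sensor noise (default sd
0.02) in the lowest/highest ~50 nm of the grid, mimicking reduced sensor
sensitivity at the spectral extremities; final clip to [0, 1].  Everything
is a pure function of the spec and seed, and cohort sample seeds derive from
(master seed, patient, image), so cohorts are reproducible independent of
generation order.

What the phantom does **not** model: biophysically accurate breast-tissue
optics, tumor-margin geometry, within-class *spectral shape* variation
(spectra are endmember × positive scalar, so SAM between same-class pixels
is ~0), camera optics and mosaic-sensor spectral sampling.  Passing tests on
phantoms therefore demonstrate the pipeline's mechanics and the direction of
the degradation/reconstruction trends, not clinical performance.

## Scaled study conditions

The end-to-end study used by the tests and the reproduction script runs at
desk scale: 20 single-image phantom patients at 64×64×31 bands, split 12/4/4
by patient, 1000 training epochs with Adam at lr 1e-3 (a rate suited to the
small 31-band network; the full-scale default stays 1e-4), evaluation every
10 epochs.  One model — trained exclusively on the default blur degradation
— serves all four experiments, and the bilinear-upsampling baseline columns
depend only on the degradation, never on the weights.  The study finishes in
roughly 10–15 minutes on one CPU.

Observed behavior at this scale: reconstruction PSNR decreases monotonically
with blur kernel size and exceeds the upsampling baseline by ~6 dB at
kernels ≥ 15; band-restricted PSNR in the noise window improves over the
noisy input at every variance; specular-region error grows from the 2×2 to
the 5×5 region at the suite's fixed seed.  The blur and noise margins are
large and stable; the specular size trend is the weakest signal — with only
four test images and randomized region placement its margin is small and
can invert for some cohort seeds.  Absolute values are far from full-scale
numbers (tiny cohort, 31 bands, 1000 epochs) and are not comparable to
clinical data.

### A known adversarial case

At dead-pixel footprints the reconstruction restores *values* better than
the corrupted upsample (lower footprint RMSE) but not *angles* (higher
footprint SAM).  This is structural: phantom spectra are endmember × scalar,
and SAM is invariant to positive per-pixel scaling, so zeroing an LR pixel
and bilinearly upsampling leaves the baseline's spectral shape at the
footprint nearly unchanged — its footprint SAM is about the whole-image
baseline SAM.  The reconstruction, by contrast, injects the exact RGB bands
into otherwise attenuated spectra, which raises its angle.  The acceptance
suite asserts the angular comparison anyway (it is the stated oracle) and
it is expected to fail under the phantom's spectral model; the RMSE
comparison and the whole-image metrics pass.

## Numerical notes

* Center crop: window starts at `ceil(Y/2) − ceil(h/2)`; the odd margin's
  extra pixel goes to the top/left.  This convention telescopes, so two
  successive crops equal one crop.
* Wavelength→band mapping: nearest center, ties to the lower index.
* ENVI I/O accepts BSQ/BIL/BIP float32/float64 and writes BSQ float32 little
  endian; the HDF5 container stores float32 reflectance plus a float64
  wavelength grid and metadata attributes.
* Degenerate inputs raise early: empty masks, zero-peak/zero-mean bands,
  colliding RGB band indices, overlapping specular regions, non-divisible
  downsampling dims.

## Limitations

The network is the minimal three-convolution variant: no multi-block stacks,
attention, adversarial losses, or band-count reduction.  Training uses
full images (448×448×384 at full scale implies full-image steps) and a
single CPU/GPU-agnostic NumPy implementation; wall-clock performance claims
are out of scope.  Radiometric calibration, hardware synchronization and
downstream tissue classification are likewise out of scope.
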