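# lumifuse

RGB-guided spatial–spectral super-resolution of reflectance hypercubes, built
for intraoperative margin-assessment imaging of resection specimens.

Hyperspectral imaging of surgical specimens trades resolution for speed:
line-scanning cameras produce rich hypercubes (~400–1000 nm, hundreds of
bands) too slowly for use during surgery, while fast snapshot cameras are
spatially coarse.  `lumifuse` reconstructs a high-resolution hypercube
(HR-HSI) from two fast acquisitions — a low-spatial/high-spectral-resolution
cube (LR-HSI) and a high-resolution RGB image (HR-RGB) — and ships everything
needed to develop and validate that reconstruction without clinical data:

* a hypercube data model with ENVI (`.hdr` + raw, BSQ/BIL/BIP) and HDF5
  container I/O, center cropping, background masking and band rendering;
* a deterministic phantom generator emulating specimen imagery (elliptical
  tissue on a black background, smooth spectrally distinct regions, sensor
  noise at the spectral extremities);
* the forward degradation models (Gaussian blur → bilinear downsample,
  RGB band extraction) and four corruption injectors (blur, band-confined
  uniform noise, dead pixels, specular-saturation plateaus);
* the three-stage reconstruction network — band-replacement fusion,
  spatial and spectral refinement convolutions — with its composite
  spatial + spectral + fused loss, written in NumPy with hand-derived,
  finite-difference-verified gradients;
* patient-grouped 60/20/20 splitting, a deterministic Adam training loop
  with dual-metric (PSNR **and** SAM) checkpointing;
* background-masked full-reference metrics (RMSE, per-band/mean PSNR,
  ERGAS, SAM) checked against naive-loop oracles;
* experiment drivers reproducing the blur / noise / dead-pixel / specular
  evaluations with a bilinear-upsampling baseline.

The model, in brief: the LR-HSI is bilinearly upsampled to the RGB's size
and the bands nearest 650/532/473 nm are overwritten with the RGB channels
(band-replacement fusion); then

    u      = ReLU(conv₃ₓ₃(fused))
    prelim = u + conv₃ₓ₃(u)
    final  = prelim + conv₃ₓ₃(prelim)

is trained with `L = L_spatial(prelim) + L_spectral(final) + MSE(final)`,
where the spatial/spectral terms are MSEs of adjacent-pixel and
adjacent-band difference maps.  Metrics exclude black background pixels.
See `docs/methods.md` for the full account.

## Worked example

```python
import lumifuse as lf

ph = lf.generate_phantom(lf.PhantomSpec(64, 64, n_bands=31, seed=7))
deg = lf.DegradationSpec()                      # 5x5 blur, sd 10, factor 4
lr = lf.make_lr_hsi(ph.cube, deg)               # snapshot-like input
rgb = lf.extract_rgb(ph.cube, deg.rgb_wavelengths)
print("reference:", ph.cube.shape, "LR-HSI:", lr.shape, "HR-RGB:", rgb.data.shape)

baseline = lf.upsample(lr, ph.cube.shape[:2])   # bilinear-only baseline
report = lf.evaluate_pair(ph.cube, baseline.data)
print(f"PSNR  {report.psnr:.2f} dB")
print(f"RMSE  {report.rmse:.4f}")
print(f"ERGAS {report.ergas:.2f}")
print(f"SAM   {report.sam:.2f} deg   ({report.n_pixels_used} tissue pixels)")
```

prints

```
reference: (64, 64, 31) LR-HSI: (16, 16, 31) HR-RGB: (64, 64, 3)
PSNR  16.83 dB
RMSE  0.1172
ERGAS 26.88
SAM   5.91 deg   (2050 tissue pixels)
```

— the bilinear baseline recovers the 64×64 specimen from its 16×16
degradation at ~17 dB masked PSNR with a 5.9° mean spectral angle; the
trained reconstruction network improves the PSNR by several dB (run
`lumifuse train`, or the study below, to see the comparison tables).

The same pipeline is scriptable from the shell:

```bash
lumifuse simulate --out cohort --patients 20 --size 64x64 --bands 31 --seed 1
lumifuse degrade  --in cohort/P000-img0.h5 --out degraded --noise-var 0.01
lumifuse evaluate --reference cohort/P000-img0.h5 --estimate degraded/lr_hsi.h5 --ratio 0.25
lumifuse train    --cohort cohort --config train.yaml --out run
lumifuse experiment blur --run run --cohort cohort --out results
```

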