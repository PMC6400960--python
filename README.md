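# netflics

Compressed-sensing fluorescence lifetime imaging, end to end: a forward
simulator of time-resolved single-pixel measurements, the classical
reconstruction baseline (per-gate total-variation inversion + lifetime
fitting), and **Net-FLICS** — a convolutional network that maps the raw
256×512 time-resolved measurement array directly to 32×32 intensity and
lifetime images, with no inverse solver and no curve fitting.

## Who this is for

Macroscopic fluorescence lifetime imaging (MFLI) with structured
illumination records, for each binary Hadamard pattern `P_k`, one
time-resolved photon histogram `S_k(t)` on a single-pixel detector. The
classical workflow recovers the image in two slow, parameter-sensitive
steps: solve `P·I(t) = S(t)` per time gate with a compressed-sensing
solver, then fit a mono-exponential `A·exp(−t/τ)` to every pixel's
temporal point spread function. This package implements that baseline
(**TVRecon**), the network that replaces it, the synthetic phantom
generator both are trained/evaluated on, and the metrics (MAE, SSIM,
per-region lifetime statistics) to compare them — for researchers
prototyping CS-FLIM reconstruction on a laptop, without instrument data.

## Worked example

```python
import numpy as np
from netflics import (TemporalAxis, gaussian_irf, build_hadamard_bank,
                      make_glyph, make_scene, simulate_sample,
                      reconstruct, mae, ssim)

axis = TemporalAxis()                    # 256 gates x 40 ps
irf = gaussian_irf(axis)                 # FWHM 0.2 ns, peak at 1.0 ns
bank = build_hadamard_bank()             # 512 sequency-ranked 32x32 patterns

scene = make_scene([make_glyph(1)], level="3", rng_seed=42)   # 400-1600 counts
meas, truth = simulate_sample(scene, bank, irf, axis, rng_seed=7)
print(meas.data.shape)                   # (256, 512) noisy photon counts

result = reconstruct(meas, bank)         # TV inversion + tail fitting
fg = truth.mask
print(f"true lifetime      {truth.lifetime[fg][0]:.3f} ns")
print(f"fitted (median fg) {np.median(result.lifetime[fg]):.3f} ns")
print(f"intensity MAE      {mae(result.intensity, truth.intensity):.2f} counts")
print(f"intensity SSIM     {ssim(result.intensity, truth.intensity, 1600):.3f}")
```

Output:

```
(256, 512)
true lifetime      0.413 ns
fitted (median fg) 0.394 ns
intensity MAE      50.68 counts
intensity SSIM     0.843
```

The scene carries a single dye with a 0.413 ns lifetime scaled to a peak
of ~1237 counts; after Poisson noise and 2× compression (512 patterns
for 1024 pixels) the classical reconstruction recovers the lifetime to
~0.02 ns (median over foreground) and the intensity image to ~4 % of the
peak per pixel.

Training and applying the network (minutes-scale preset):

```python
from netflics import preset_config, build_model, train, predict, make_training_arrays
cfg, n_train, n_val = preset_config("smoke")
# simulate n_train noiseless + n_val noisy samples as above, then:
model = build_model(cfg, bank)           # physics-initialized common segment
trained = train(model, train_arrays, val_arrays, resample_noise=True)
results = predict(trained, [meas])       # <3 ms per sample
```

A `flics` command line wraps the same stages
(`flics simulate | reconstruct-tv | train | predict | evaluate | run`)
around an HDF5 dataset container and YAML run configs.

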