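# Methods

## The measurement model

The package simulates a structured-light single-pixel fluorescence
lifetime imager. A scene is a pair of 32×32 images: CW intensity `I`
(photon counts, defined throughout as the **time-integrated** counts of a
pixel) and lifetime `τ` (ns). Each pixel emits a mono-exponential decay
`A·exp(−t/τ)` sampled on `n_gates` uniform time gates, convolved with the
instrument response function (IRF). The per-pixel temporal kernel
(decay ⊗ IRF, truncated to the gate window) is renormalized to unit sum
before scaling by `I`, so the noiseless chain conserves photons exactly —
the alternative (normalizing the decay before convolution) loses the
convolution tail that falls past the last gate (~5·10⁻⁴ of the mass for
τ = 1.5 ns) and would make exact conservation checks meaningless.

Binary illumination patterns are binarized rows `(H+1)/2` of a Sylvester
Hadamard matrix of order 1024, reshaped to 32×32 and ranked by *sequency*
(sign-change count, the Walsh analogue of spatial frequency); the
all-ones (full-field) pattern ranks first. One measurement is the
pattern-weighted sum of all pixel TPSFs at one gate; Poisson noise is
applied to every gate×pattern count. Defaults follow the acquisition
geometry the method targets: 256 gates × 512 patterns.

Quantities the acquisition does not pin down are explicit, documented
choices:

| parameter | default | rationale |
|---|---|---|
| gate width | 40 ps (10.24 ns window) | resolves 0.3–1.5 ns decays with a long tail, typical of PMT-TCSPC gating |
| IRF | Gaussian, FWHM 0.2 ns, peak 1.0 ns | typical system response; replaceable by a measured two-column ASCII curve |
| pattern subset | first 512 in sequency order | lowest spatial frequencies carry most glyph energy |
| pair mode | complementary-pattern differencing | recovers signed Hadamard weights; used by the reduced 400-pair configuration |

## The scene generator

Scenes emulate handwriting-like phantoms: 1–3 procedurally drawn glyphs
(Bezier strokes, ellipse arcs, bars on a 28×28 canvas, lightly blurred,
5–60 % support), each independently rotated (a multiple of 90° plus
U(−15°, 15°), nearest-neighbour, support re-thresholded at 0.1), placed
at a uniform offset, and scaled so its peak CW intensity is uniform in
the photon level's range: 25–100 (level 1), 100–400 (level 2), 400–1600
(level 3), 25–1600 (`full`, the default). Each glyph carries a single
lifetime drawn uniformly from 0.3–1.5 ns (one glyph ≙ one dye); a
per-pixel-lifetime mode exists behind a flag. Overlapping glyphs sum
their intensities and mix lifetimes by intensity-weighted average, and
the summed image is clipped at the level maximum. Background is exactly
zero in both images. Train/val/test splits draw from disjoint seed
streams. An IDX (idx3-ubyte) loader accepts a real glyph bank as an
alternative to the procedural generator.

What the generator does **not** emulate: optical blur and tissue
scattering, detector afterpulsing and dark counts, laser jitter (handled
only by the rising-edge alignment utility), wavelength channels, and
bi-exponential decays. Passing tests therefore demonstrate correctness of
the algorithms under idealized single-dye phantom statistics, not
instrument-grade performance.

## TVRecon — the classical baseline

Per gate `t`, the inverse problem `P·x = s(t)` is solved with
anisotropic total-variation regularization,

    min_x  TV(x) + (μ/2)·‖P x − s‖²,   optionally x ≥ 0,

by an augmented-Lagrangian splitting: `w` carries the image gradients
(soft shrinkage with threshold 1/β), and nonnegativity is a separate
splitting variable updated by exact projection. Each outer iteration runs
`n_inner` exact alternating block minimizations at fixed multipliers
(each block update is an exact minimizer, so the augmented Lagrangian is
non-increasing within an outer iteration — a tested invariant), followed
by multiplier ascent. The x-update solves a fixed SPD system, factorized
once and applied to all gates (and all scenes of a batch) as one GEMM;
converged gate columns retire from the iteration.

Numerical choices that matter:

* **Signal conditioning.** Each gate's signal is scaled to unit pixel
  scale (`2·max|s|/n_px` estimates the peak pixel value since a pattern
  sums ~half the pixels). TV is 1-homogeneous, so this is equivalent to a
  per-gate fidelity weight `μ/c_g` — which is exactly the 1/variance
  weighting Poisson noise calls for (σ² ≈ mean counts ∝ c_g). It also
  puts the μ scale on O(1) images, where the default μ = 2⁻² balances
  noise suppression against foreground shrinkage across the generator's
  photon range. For noiseless complete-bank data (inversion exactness
  checks) a fidelity-dominated weight μ = 2⁴ is the appropriate setting;
  with the noisy-data default the ~5·10⁻³ residual smoothing bias is
  deliberate regularization, not solver error.
* Zero initialization everywhere; stopping at per-gate relative change
  < 10⁻⁴ or 150 outer iterations (convergence is typically reached at
  80–110; the solver runs in single precision, where much longer runs
  slowly accumulate multiplier round-off). At very large μ the splitting
  converges slowly and the relative-change rule can fire early — a known
  limitation of that stopping criterion; μ ≲ 2⁴ avoids it.
* Intensity is the time-sum of the reconstructed cube. Lifetime is fitted
  only on pixels with intensity ≥ 0.1 × the image maximum; background
  lifetime is exactly 0.
* Lifetime fitting: ordinary least squares of log counts on time, from 5
  gates past the TPSF peak to the last gate with counts ≥ max(2, 1 % of
  peak); `τ = −1/slope`. Fewer than 3 usable gates, a non-decaying slope,
  or an unphysically slow fit (τ̂ > 5 ns) flag the pixel invalid (τ = 0).
  The 2-count floor keeps dim TV-denoised tails fittable (a 5-count floor
  voids many low-peak pixels); raw un-denoised histograms warrant a
  higher floor. The fit is deliberately *unweighted*: counts-weighted log
  fitting emphasizes the peak region, where TV reconstruction bias is
  largest, and measured ~3× worse on reconstructed TPSFs. The fit is
  reliable for pixels carrying ≳400 counts; below that, TV suppression of
  the dim decay tails distorts the temporal shape and errors grow
  sharply.
* Rising-edge alignment (for jitter-affected experimental traces) shifts
  a measurement set so the first gate at ≥ 5 % of the full-field trace's
  maximum matches a simulated reference; shifts zero-pad, never wrap.

## The network

Input is the raw 256×512 measurement array; outputs are the 32×32
intensity and lifetime images. Three segments:

* **Common segment** — a fully connected measurement→pixel map shared
  across gates (equivalently a kernel-1 Conv1D over the gate sequence),
  transposed into a pixel-leading 32×32×256 block, then a 1×1
  convolutional mixing layer (+BN+ReLU). The dense layer is seeded with
  the Hadamard backprojection `H_selᵀ(2s − s_dc)` — the least-squares
  inverse on the sampled subspace — so the block starts as a physical
  TPSF estimate. The 1/order normalization of the backprojection is
  deliberately omitted: downstream batch norm absorbs scale, while O(1)
  weight entries survive RMSprop's per-parameter step size.
* **Intensity head** — one ResBlock and one ReconBlock on the mixed
  features, plus a residual skip: the gate-sum of the common block
  (divided by the pixel count) is itself an unbiased intensity estimate,
  so the head only learns a correction. ReconBlock output convolutions
  are initialized near zero so training starts at the physics baseline.
* **Lifetime head** — a 1D convolution along the gate axis of the block
  (4 filters, kernel 32, stride 32 by default), then two ResBlocks and
  two ReconBlocks, with a fixed 1.5 ns output scale.

ResBlocks are two 3×3 conv+BN+ReLU with identity skip; ReconBlocks are
the wide-kernel → 1×1 bottleneck → single-channel stack (64@11×11 →
32@1×1 → 1@7×7 by default; the scaled-down presets use 16@5×5 → 8@1×1 →
1@5×5). Everything is NumPy with explicit forward/backward passes (each
checked against central finite differences in the test suite), which
keeps runs bit-reproducible on one device.

Training minimizes `MSE(intensity) + 10⁵·MSE(lifetime)` with RMSprop
(ρ = 0.9), learning rate 10⁻³ halved every 10 epochs, early stopping when
the validation lifetime MAE has not improved for `patience` epochs, and
restoration of the best-epoch state. Targets keep background lifetime at
exactly 0, so the network learns to silence background itself — its
outputs need no post-processing.

**Noise resampling.** Training inputs can be stored as noiseless photon
means with a fresh Poisson realization drawn every epoch. Each draw comes
from exactly the acquisition noise model, so a scene set of hundreds
behaves like an unbounded stream of noisy samples; this is the package's
sample-efficiency substitute for a tens-of-thousands fixed training set
and is what the scaled-down presets use.

**Presets.** `full` (32 000/8 000 samples, full ReconNet widths) is the
full-scale recipe; `desk` (2 000/500, ≤30 epochs) and `smoke`
(800/200 scenes, ≤14 epochs, ~12 min on one CPU core) trade capacity and
sample count for runtime. The problem sizes used by the test suite and by
`scripts/acceptance.py` are the `smoke` preset and a 40-scene test batch
— the package's own minutes-scale defaults.

## Evaluation

MAE is the mean over all 1024 pixels (background included — exactly where
low-intensity pixels hurt lifetime estimation); a foreground-only MAE is
reported alongside. SSIM uses a 7×7 Gaussian window (σ = 1.5), K1/K2 =
0.01/0.03, with data ranges 1600 (intensity) and 1.5 ns (lifetime) — the
generator maxima. Region statistics (mean ± population SD over a mask)
support phantom-style per-region tables. Reports serialize to CSV (per
sample) and JSON (aggregates), with optional photon-level stratification.

## Known limitations

* The classical baseline's all-pixel error metrics depend strongly on
  scene composition (multi-glyph overlap regions mix lifetimes and defeat
  mono-exponential fitting; faint glyphs below the background threshold
  are zeroed), so absolute MAE values are only comparable between methods
  on the same batch, not across generators with different composition
  choices.
* Single wavelength channel; no bi-exponential/FRET-fraction fitting.
* The network presets target CPU minutes; at these sizes the network
  reliably beats the classical baseline on lifetime but its intensity MAE
  remains above the classical baseline's on bright scenes (its SSIM is
  higher — errors are spatially smoother).
* Batch-norm statistics make training-mode and inference-mode outputs
  differ slightly; all reported metrics use inference mode with running
  statistics.
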