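# Methods

This note documents the models, numerical choices and limitations behind
`cineclust`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Phantom model

The myocardium is an annulus (default inner/outer radii 48/72 px on a
224×224 grid; 26/40 px on the 128×128 pipeline default) whose radius scales
sinusoidally over the cycle,

```
s(t) = 1 − A·(1 − cos 2πt/T)/2,        t = 0 … T−1,
```

so end-diastole (`s = 1`) is frame 0 and end-systole (`s = 1 − A`) is
mid-cycle. `A` is the contraction amplitude as a fraction of the outer
radius (default 0.1, a realistic ~10% radial excursion) and `T = 20` frames
per cycle. Image texture is synthesized as a handful of random plane waves
in *material* coordinates, so it advects exactly with the tissue and gives
flow estimators trackable structure; tissue classes (background / blood
pool / myocardium) are smooth-edged level sets of the material radius.

A lesion is a disc in material coordinates with two effects: a constant
intensity offset `Δ ∈ [−1, 1]` (positive = bright, edema-like; negative =
dark, infarct-like — the sign convention is ours, chosen because edema is
bright on T2-weighted contrast while chronic infarcts are not enhanced on
cine) and motion damping `d ∈ [0, 1]` that scales the local displacement by
`1 − d` (1 = akinetic). The deformation with a damped inclusion is inverted
per frame by a 3-step fixed-point iteration, which converges at cardiac
amplitudes; the analytic backward displacement field between consecutive
frames is returned as ground truth and reproduces the next frame under
warping with mean absolute error below 0.05 (tested).

Noise is additive Gaussian, clipped to [0, 1]; the pathology map is the
time-union lesion support blurred with a σ = 2 px Gaussian and rescaled to
[0, 1]. Degradation is a bicubic downsample/upsample round trip
(default 128 → 64 → 128 through factor 2; a 256 grid passes through 128)
plus clipped Gaussian noise. Augmentation draws a rotation uniform in ±20°,
an elastic displacement field (white noise smoothed with σ = 8 px and
rescaled to a 5 px standard deviation) and a multiplicative intensity shift
within ±10%; image and mask share the geometric transform (bilinear vs
nearest-neighbour sampling).

What the phantom does **not** model: through-plane motion, MR physics
(k-space, coils, bias fields), papillary muscles, realistic lesion
morphology, or the 17-segment anatomy. Passing tests therefore demonstrate
correctness of the *pipeline mechanics* — flow, integral, clustering,
metrics — under a controlled motion model, not clinical performance.

## Optical flow

A classical coarse-to-fine Horn–Schunck solver: 3 pyramid levels
(factor 2, bilinear anti-aliased), 50 Jacobi relaxation iterations per
level with the standard weighted 8-neighbour average, and 3 re-linearization
(warp) passes per level. Intensities are scaled to 0–255 internally so the
default regularization weight α = 15 has its conventional magnitude. The
solver is fully deterministic. Flow follows the backward-warping
convention: `flow[t]` sampled at pixel `p` points to the position of `p`'s
material point in frame `t`, i.e. `warp(frame_t, flow[t]) ≈ frame_{t+1}`.
Constant (zero-variance) frame pairs yield zero flow with a warning rather
than an error. On noise-free phantoms the estimate correlates with the
analytic truth at r ≥ 0.7 over the myocardium and is cross-checked against
an independent TV-L1 implementation (tested).

## Motion integral and phase normalization

The consistency integral is discretized as a sum over frame pairs
(Δt = 1 frame) of the squared spatial gradient of both flow components,
using central differences on an edge-replicated grid; a global translation
contributes nothing, and the 5×5 unit-shear case evaluates to exactly 1 on
interior pixels (tested). Phase normalization computes each frame pair's
global motion energy (mean squared flow magnitude), discards pairs with
energy strictly above the chosen quantile (default 0.8) of the cycle's
energies — ties kept, so a flat energy profile loses nothing — and rolls
the phase origin to the minimum-energy pair. Because the integrand is
non-negative and normalization only removes pairs, the healthy-tissue
motion integral can only decrease; the acceptance script reports the
observed relative drop (~20% under default conditions).

## Descriptor, affinity and clustering

`D_s = λ_s·S + λ_t·I_motion` with `S` the temporal mean intensity and
`λ_s = λ_t = 0.5`. With standardization on (default), each term is centred
on its ROI median and divided by its **median absolute adjacent-pixel
difference** inside the ROI. This local calibration — in the spirit of
self-tuning spectral clustering — is deliberate: the affinity bandwidth
σ = 1.5 then measures descriptor *jumps in units of healthy-tissue local
contrast*. A global z-score would let the pathological tail inflate the
scale, leaving lesion boundaries only ~2 standard deviations strong, and
the balanced-cut objective would then prefer cheap angular cuts of the
annulus over isolating a small lesion.

The affinity graph connects ROI pixels within Chebyshev radius 3 (the dense
`W` of the formula is quadratic in ROI size and intractable for full
images; `max_nodes` = 20 000 guards memory), with
`W_ij = exp(−|D_s(i)−D_s(j)|²/2σ²)`, `W_ii = 1`, `D = diag(row sums)` and
`L = D − W` exposed exactly in that combinatorial form.

Spectral clustering embeds nodes with the eigenvectors of the `k` smallest
generalized eigenvalues `L v = λ D v` (computed through the symmetric
normalization; dense LAPACK below 3 000 nodes, Lanczos above), row-
normalized, followed by seeded k-means; soft memberships are the softmax of
negative squared distances to the centroids (temperature 1), which is what
the entropy measure needs. The generalized problem is used because it is
the standard relaxation of the minimum *normalized* cut, the partition
criterion we validate against. For `k = 2` the package uses the classical
Shi–Malik sweep cut — thresholding candidate Fiedler vectors (random-walk,
symmetric and unnormalized) where the normalized cut is minimal — plus
deterministic local refinement (greedy single-node moves; pair swaps and
multi-threshold restarts on graphs up to 64 nodes). This two-way variant
agrees with exhaustive minimum-normalized-cut search on ≥ 95% of small
random connected graphs (tested); plain k-means on a 2-D embedding does
not.

`k` defaults to 6: a contracting annulus supports roughly four
low-eigenvalue angular harmonics, so a pathology cluster only gets an
eigenvector of its own once `k` exceeds them. σ = 1.5, DBSCAN ε = 2.5 px
and 5 minimum samples are the method's stated operating point and are not
touched. DBSCAN runs per spectral cluster on pixel coordinates only: it
splits spatially disconnected fragments and demotes density-unreachable
pixels to noise (−1); noise is excluded from entropy and compactness means.
Compactness is the pooled explained-variance percentage
`100·(1 − SSW/SST)` of the descriptor over non-noise nodes, clipped to
[0, 100].

## Objective terms

All loss terms are pure functions of supplied arrays; no gradients or
training. The adversarial value is the standard GAN objective
`E[log D(real)] + E[log(1 − D(fake))]` on given discriminator outputs,
clamped at 1e−7 for numerical safety. SSIM uses the conventional 11×11
Gaussian window (sd 1.5), k₁ = 0.01, k₂ = 0.03, population moments, border
windows excluded from the mean; it matches an independent reference
implementation to 1e−6 (tested). The pathology consistency term normalizes
each non-negative map (+1e−8 smoothing) to a pixel distribution and returns
`D_KL(P‖Q)` in nats. The topology loss compares the Laplacian of a
Gaussian affinity over latent features (same kernel form as the pixel
graph) with the Laplacian of binary cluster co-membership via the squared
Frobenius norm, weighted by λ_topo = 0.2. The curriculum selects samples
with membership entropy strictly below δ, where δ anneals 0.5 → 0.1 over
50 epochs (linear by default; a cosine mode is provided because the
protocol description is ambiguous between the two) and the
supervised/consistency mixing weight α anneals linearly 1 → 0 over the run.
The total objective is the weighted sum of the six terms (unit weights
except λ_topo; the motion map enters through its ROI mean — the only
reduction that keeps a scalar objective well-typed).

In the orchestrated pipeline the adversarial term is evaluated on neutral
discriminator outputs (0.5), since no discriminator exists at this scale;
it contributes the constant 2·ln 0.5.

## Pipeline and reproducibility

`run_pipeline` executes phantom → degradation → flow → phase normalization
→ motion integral → descriptor → affinity → spectral + DBSCAN → metrics →
losses, writing NIfTI volumes, a label map, a metrics CSV, a losses JSON
and a manifest (config hash, seed, versions, stage timings). The analysis
ROI is the set of pixels that are myocardial in **every** frame, so each
node has cycle-long motion statistics; the time-union mask would mix
background into boundary pixels. The degraded copy feeds the image-quality
metrics (PSNR/SSIM), while the analysis chain runs on the clean sequence —
the enhancement step that would bridge the two is a learned component
outside this package's scope. Everything is seeded; two runs with the same
config and seed produce byte-identical metric CSVs (tested). Default
problem sizes (128×128, 20 frames; 20 phantoms in the recovery experiment;
50 graphs in the oracle comparison) keep a full validation run to a couple
of minutes on one CPU.

## Known limitations

- Flow is 2-D, skip-1 only; large displacements beyond the pyramid range
  (~8 px) are not recovered.
- The motion integral marks motion *heterogeneity*; a lesion moving rigidly
  with its surroundings but with altered intensity is found through the
  appearance term only.
- Entropy is computed from the spectral soft memberships; after DBSCAN
  refinement only hard labels exist, so refined-partition entropy reduces
  to one-hot values.
- Cluster count `k` is fixed per run, not model-selected.
- The concordance operation matches partitions by optimal assignment;
  anatomical reference partitions (e.g. standardized ventricular segments)
  are not shipped.
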