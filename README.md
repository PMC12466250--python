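# cineclust

Motion-consistency mapping and spatio-temporal clustering for cardiac
cine-MRI lesion analysis, exercised end to end on a synthetic beating-heart
phantom.

## The problem

In cine-MRI the heart is imaged as an ordered stack of 2-D frames over one
cardiac cycle. Myocardial lesions (infarct, edema) show up in two ways:
their intensity differs from healthy muscle, and their local motion is
abnormal — infarcted tissue is hypokinetic or akinetic while the
surrounding wall keeps contracting. `cineclust` turns both cues into an
unsupervised segmentation:

1. **Dense optical flow** `V_t` between consecutive frames (a deterministic
   coarse-to-fine Horn–Schunck solver).
2. **Motion-consistency integral**
   `I_motion(x, y) = Σ_t ‖∇V_t(x, y)‖² Δt` — the time-accumulated squared
   *spatial* gradient of the flow. Coherently moving tissue scores low;
   motion abnormalities score high. Phase normalization first excludes the
   frame pairs at the global contraction/relaxation peaks so that
   end-systole and end-diastole do not masquerade as abnormalities.
3. **Hybrid descriptor** `D_s = λ_s · SpatialIntensity + λ_t · I_motion`
   mixing appearance (temporal mean intensity) and motion.
4. **Gaussian affinity graph** over ROI pixels,
   `W_ij = exp(−|D_s(i) − D_s(j)|² / 2σ²)` with `σ = 1.5`, Laplacian
   `L = D − W`, **spectral clustering**, then **DBSCAN refinement** in pixel
   space (`ε = 2.5` px, 5 minimum samples) that splits fragments and labels
   stray pixels as noise.
5. **Quality measures**: per-pixel membership entropy, explained-variance
   compactness, Dice/IoU/sensitivity/F1, PSNR/SSIM, motion-compensated
   temporal consistency, and partition concordance.

The package also provides, as pure functions, every term of the training
objective the surrounding learning system would optimize (adversarial
value, SSIM loss, pathology-map KL consistency, graph-Laplacian topology
loss, entropy-thresholded curriculum selection with annealed `δ` and `α`
schedules) — no networks are trained here.

Because clinical cine data cannot ship with a library, the `phantom` module
generates a contracting myocardial annulus with analytically known motion,
configurable lesions (intensity shift + motion damping), pathology maps and
ground-truth masks/flow, plus the bicubic degradation and
rotation/elastic/intensity augmentation operators used in training
protocols.

## Worked example

```bash
cineclust run-all --out out/
```

generates the default phantom (128×128, 20 frames, one bright lesion with
motion damping 0.8), estimates flow, clusters, and evaluates against the
known truth. It prints, among others:

```
"dice": 0.8969,
"iou": 0.8131,
"sensitivity_pct": 96.67,
"f1": 0.9667,
"cluster_entropy": 1.4286,
"compactness_pct": 79.12,
"temporal_consistency_truth_flow": 0.98,
"temporal_consistency_est_flow": 0.9914,
"psnr_degraded_db": 30.63,
"ssim_degraded": 0.755
```

Reading: the refined cluster best matching the true lesion overlaps it with
Dice 0.90; the partition explains ~79% of descriptor variance; warping each
frame's truth mask with the analytic (resp. estimated) flow reproduces the
next frame's mask with Dice 0.98 (0.99); and the simulated
acquisition-quality gap (bicubic 128→64→128 round trip + noise) costs
~30.6 dB PSNR / 0.76 SSIM relative to the clean sequence. `out/` contains
the NIfTI sequence and masks, the cluster label map, a losses JSON, a
metrics CSV and a provenance manifest; the same Python API is available via
`cineclust.run_pipeline`.

The same stages are available individually as `simulate`, `degrade`,
`flow`, `cluster`, `losses` and `evaluate` subcommands, configurable from a
YAML file (see `cineclust.config.PipelineConfig`).

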