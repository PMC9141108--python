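# bottleinspect

Moving-impurity detection for liquid-filled bottles (distilled spirits,
pharmaceutical liquids, bottled water) inspected on back-lit machine-vision
stations.  After a bottle is flipped, genuine impurities — glass chips,
hairs and fibres, insect fragments, metal scraps — move through the liquid,
while wall stains and scratches stay put.  The package segments those moving
targets from 8-bit grayscale frame sequences and separates them from rising
air bubbles, the main false-alarm source.

It is written for vision engineers building inspection lines and for
researchers benchmarking background-subtraction variants on small moving
targets.

## Method

Detection fuses two complementary motion cues:

1. **Ambient-compensated frame differencing.**  A pixel is moving when
   `|f_t − f_{t−1}| > T_c + T_r`, where `T_r` is the mean absolute
   difference over the ROI.  A global illumination step raises `T_r` by
   exactly the step size, so uniform light changes produce an empty motion
   mask.

2. **Adaptive per-pixel Gaussian mixture background model.**  Each pixel
   holds `K ∈ [K_min, K_max]` weighted Gaussians `(w_i, μ_i, σ_i²)` ranked
   by `w/σ`.  A value `x` matches a component when `|x − μ| ≤ D σ`; the
   background is the smallest prefix whose cumulative weight exceeds `T_b`
   (matching beyond it, or not at all, marks foreground).  The matched
   component follows `μ ← (1−ρ)μ + ρx`, `σ² ← (1−ρ)σ² + ρ(x−μ)²`.  Unlike
   the classic fixed-K mixture, components unmatched for `V_max` consecutive
   frames are pruned, components with means within `ε` gray levels are
   merged, new components are seeded from the lowest-ranked one
   (`w = w_k(1−β)`, `σ² = (1+β)σ_k²`), and the learning rate is coupled to
   the motion mask through a per-pixel counter `G`:
   `α_eff = (2G/m)·α_base`, with `G` rising inside moving regions and
   decaying elsewhere.

The motion mask is morphologically closed and ANDed with the mixture
foreground: differencing alone sees only the leading/trailing edges of a
uniform body (the "hole" phenomenon) and background subtraction alone is
fooled by light changes and ghosts; the closed-motion AND keeps the complete
target pixels while vetoing both failure modes.  Connected components become
minimum-outer-rectangle detections; each crop is described by a
multi-scale-block HOG descriptor (orientation-interpolated voting, L2-Hys
normalisation) and classified impurity-vs-bubble by an RBF-kernel SVM
(`k(x,y) = exp(−‖x−y‖²/2σ²)`) with seeded cross-validated hyperparameters.

Evaluation follows the field's standard statistics: pixel precision
`Pa = M/(M+N)`, recall `Pb = M/(M+L)`, comprehensive index
`Pc = 2·Pa·Pb/(Pa+Pb)`, whole-bottle recognition rate
`η = (n₁+n₂)/(m·n₃)`, and Knapp–Kushner quality factors `FQ = q/N × 10`
with the machine/manual efficiency ratio `R = FQB(7,10)/FQA(7,10) × 100%`.

A synthetic scene generator renders bottle interiors with drifting
specks/hairs/chips, bright-rim elliptical bubbles, static stains, scheduled
illumination steps and sensor noise — with exact per-frame ground truth — so
the whole pipeline is testable without factory footage.

## Worked example

Render a 60-frame synthetic scene, run the fused detector, and score its
masks against the exported ground truth:

```bash
bottleinspect simulate --out demo/scene --frames 60 --shape 96 96 \
    --particles 2 --bubbles 1 --stains 1 --seed 7 --write-masks
bottleinspect detect --input demo/scene --out demo/run --roi full
bottleinspect eval-pixels --pred demo/run/masks --truth demo/scene/masks
```

which prints

```
wrote 60 frames to demo/scene
{"config_hash": "e810150bf3986211", "detections_per_class": {"unclassified": 147},
 "n_detections": 147, "n_frames": 60, "roi": [0, 96, 0, 96], "warmup_frames": 10}
{"L": 664, "M": 2771, "N": 27, "Pa_pct": 99.0, "Pb_pct": 80.7, "Pc_pct": 88.9}
```

147 boxes were detected over the 49 post-warm-up frames (the two drifting
particles and the bubble, one box each per frame, and nothing on the stain).
At pixel level the detector recovered the moving objects with 99.0%
precision and 80.7% recall (`Pc` 88.9%); the missed pixels are mostly bubble
rim sections that overlap their own position between frames.  Train a
classifier with `bottleinspect train --manifest crops.csv --out model.joblib`
and pass `--model model.joblib` to `detect` to label each box
impurity/bubble.

The same flow is available as a library:

```python
import bottleinspect as bi
from bottleinspect.scenes import benchmark_scene

frames, truth = bi.generate_sequence(benchmark_scene(seed=0))
result = bi.run_detection(bi.RunConfig(roi="full"), frames=frames)
report = bi.aggregate_pixel_metrics(zip(result.fused_masks[10:], truth.masks[10:]))
print(f"Pa {report.Pa:.3f}  Pb {report.Pb:.3f}  Pc {report.Pc:.3f}")
# Pa 0.943  Pb 0.906  Pc 0.924
```

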