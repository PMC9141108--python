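"""Canonical synthetic study conditions.

``benchmark_scene`` is the package's reference end-to-end scenario: a
200-frame 128x128 bottle interior with three moving impurities (a speck, a
hair and a glass chip), two rising bubbles, two static wall stains and one
-30 gray-level light-to-dark step at frame 124, under sigma = 2 sensor
noise.  Impurity speeds are chosen so the per-frame displacement is at least
the body size — the regime a flipped bottle produces while particles sink —
which is where AND-fusion of background subtraction and frame differencing
is designed to operate.  ``crop_dataset`` renders labelled single-object
crops at the 3:1 impurity:bubble ratio used for classifier training.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .synthetic import (
    BubbleSpec,
    ParticleSpec,
    SceneConfig,
    StainSpec,
    generate_sequence,
)


def benchmark_scene(seed: int = 0) -> SceneConfig:
    """The reference 200-frame detection scenario (see module docstring)."""
    return SceneConfig(
        frame_shape=(128, 128),
        n_frames=200,
        particles=[
            ParticleSpec("speck", "dark", size=3.0, start_position=(20.0, 30.0),
                         velocity=(3.0, 1.5), jitter_sigma=0.3),
            ParticleSpec("hair", "dark", size=9.0, start_position=(60.0, 15.0),
                         velocity=(2.5, 1.0), jitter_sigma=0.3, orientation_deg=0.0),
            ParticleSpec("chip", "dark", size=4.0, start_position=(90.0, 80.0),
                         velocity=(3.5, -2.0), jitter_sigma=0.3),
        ],
        bubbles=[
            BubbleSpec(radius=4.0, eccentricity=0.5, rise_speed=3.0, wobble_sigma=0.5,
                       rim_brightness=60.0, start_position=(110.0, 40.0)),
            BubbleSpec(radius=5.0, eccentricity=0.3, rise_speed=2.5, wobble_sigma=0.5,
                       rim_brightness=60.0, start_position=(70.0, 95.0)),
        ],
        stains=[
            StainSpec(position=(25, 100), size=6.0, intensity_offset=-40.0),
            StainSpec(position=(105, 20), size=5.0, intensity_offset=-40.0),
        ],
        illumination_schedule=[(124, -30.0)],
        noise_sigma=2.0,
        background_level=180.0,
        seed=seed,
    )


def benchmark_report(seed: int = 0) -> dict:
    """Run the fused detector over the reference scene and measure it.

    Returns pooled pixel precision/recall/comprehensive index over the
    post-warm-up frames, the number of detections that touch a stain but no
    true object, and the illumination burst ratio (max fused foreground area
    in the 10 frames from the light step over the mean area in the 10 frames
    before it).
    """
    from skimage import draw as skdraw

    from .evaluation import aggregate_pixel_metrics
    from .gmm import extract_boxes
    from .pipeline import RunConfig, run_detection

    cfg = benchmark_scene(seed)
    frames, gt = generate_sequence(cfg)
    rc = RunConfig(roi="full", seed=seed)
    res = run_detection(rc, frames=frames)
    warm = rc.init_frames
    agg = aggregate_pixel_metrics(zip(res.fused_masks[warm:], gt.masks[warm:]))

    stain = np.zeros(cfg.frame_shape, dtype=bool)
    for st in cfg.stains:
        rr, cc = skdraw.disk(st.position, st.size / 2.0 + 1, shape=cfg.frame_shape)
        stain[rr, cc] = True
    # a detection is stain-caused only if no true object explains it: frame
    # differencing responds to the supports at both t-1 and t, so a box that
    # touches either frame's objects is motion-caused, not stain-caused
    stain_fp = 0
    for r in res.records:
        box = np.zeros_like(stain)
        box[r.box[0]:r.box[1], r.box[2]:r.box[3]] = True
        t = r.frame_index
        explained = (box & (gt.masks[t] | gt.masks[max(t - 1, 0)])).any()
        if (box & stain).any() and not explained:
            stain_fp += 1

    step_frame = cfg.illumination_schedule[0][0]
    areas = res.fused_masks.sum(axis=(1, 2))
    pre = float(areas[step_frame - 10:step_frame].mean())
    post = float(areas[step_frame:step_frame + 10].max())
    return {
        "Pa": agg.Pa, "Pb": agg.Pb, "Pc": agg.Pc,
        "n_eval_frames": int(cfg.n_frames - warm),
        "stain_false_detections": stain_fp,
        "burst_ratio": post / pre if pre > 0 else float("inf"),
        "n_detections": len(res.records),
    }


def classifier_report(seed: int = 0, n_impurity: int = 300, n_bubble: int = 100,
                      test_fraction: float = 0.25) -> dict:
    """Train the HOG-SVM on synthetic crops and measure held-out accuracy.

    Crops are generated at the 3:1 design ratio, split stratified by class,
    and the fitted classifier is evaluated on the held-out quarter.
    """
    from sklearn.model_selection import train_test_split

    from .classifier import ImpurityBubbleClassifier, evaluate_classifier

    crops, labels = crop_dataset(n_impurity, n_bubble, seed=seed)
    idx = np.arange(len(crops))
    tr, te = train_test_split(idx, test_size=test_fraction, stratify=labels,
                              random_state=seed % (2**31))
    clf = ImpurityBubbleClassifier(seed=seed % (2**31)).fit(
        [crops[i] for i in tr], [labels[i] for i in tr])
    cm = evaluate_classifier(clf, [crops[i] for i in te], [labels[i] for i in te])
    return {
        "impurity_accuracy": cm.per_class_accuracy["impurity"],
        "bubble_accuracy": cm.per_class_accuracy["bubble"],
        "overall_accuracy": cm.overall_accuracy,
        "n_train": len(tr), "n_test": len(te),
        "C": clf.C_, "sigma": clf.sigma_,
    }


def _render_single(spec, shape: Tuple[int, int], background: float,
                   noise_sigma: float, seed: int) -> np.ndarray:
    """One noisy crop containing a single centred object."""
    cfg = SceneConfig(
        frame_shape=shape, n_frames=2, noise_sigma=noise_sigma,
        background_level=background, seed=seed,
        particles=[spec] if isinstance(spec, ParticleSpec) else [],
        bubbles=[spec] if isinstance(spec, BubbleSpec) else [],
    )
    frames, gt = generate_sequence(cfg)
    rec = gt.objects[0][0]
    r0, r1, c0, c1 = rec.box
    pad = 3
    return frames[0, max(r0 - pad, 0):r1 + pad, max(c0 - pad, 0):c1 + pad]


def crop_dataset(n_impurity: int = 300, n_bubble: int = 100, seed: int = 0,
                 noise_sigma: float = 2.0) -> Tuple[List[np.ndarray], List[str]]:
    """Labelled single-object crops at the 3:1 impurity:bubble design ratio.

    Impurities draw uniformly over the three shape kinds, sizes 3-9 px and
    both polarities (mostly dark); bubbles draw radius 4-10 px, eccentricity
    up to 0.7 and rim brightness 40-90 gray levels.  Background level varies
    per crop (160-200) and Gaussian sensor noise of ``noise_sigma`` is added.
    """
    rng = np.random.default_rng(seed)
    crops: List[np.ndarray] = []
    labels: List[str] = []
    shape = (36, 36)
    for i in range(n_impurity):
        kind = ("speck", "hair", "chip")[int(rng.integers(0, 3))]
        spec = ParticleSpec(
            shape_kind=kind,
            polarity="dark" if rng.random() < 0.8 else "bright",
            size=float(rng.uniform(3.0, 9.0)),
            start_position=(float(rng.uniform(14, 22)), float(rng.uniform(14, 22))),
            velocity=(0.0, 0.0),
            contrast=float(rng.uniform(80, 140)),
            orientation_deg=float(rng.uniform(0, 180)),
        )
        crops.append(_render_single(spec, shape, float(rng.uniform(160, 200)), noise_sigma,
                                    int(rng.integers(0, 2**31 - 1))))
        labels.append("impurity")
    for i in range(n_bubble):
        spec = BubbleSpec(
            radius=float(rng.uniform(4.0, 10.0)),
            eccentricity=float(rng.uniform(0.0, 0.7)),
            rise_speed=0.0, wobble_sigma=0.0,
            rim_brightness=float(rng.uniform(40, 90)),
            start_position=(float(rng.uniform(14, 22)), float(rng.uniform(14, 22))),
        )
        crops.append(_render_single(spec, shape, float(rng.uniform(160, 200)), noise_sigma,
                                    int(rng.integers(0, 2**31 - 1))))
        labels.append("bubble")
    return crops, labels
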