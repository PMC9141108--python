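"""Synthetic scene generator: rendering, motion, ground truth, determinism."""

import numpy as np
import pytest
from scipy import ndimage

from bottleinspect.synthetic import (
    BubbleSpec,
    ConfigurationError,
    GroundTruth,
    ParticleSpec,
    SceneConfig,
    StainSpec,
    generate_sequence,
    illumination_step,
    render_object,
    read_sequence,
    write_sequence,
)


def test_empty_noise_free_scene_is_constant_with_empty_masks():
    cfg = SceneConfig(frame_shape=(20, 20), n_frames=5, noise_sigma=0.0,
                      background_level=150.0, seed=3)
    frames, gt = generate_sequence(cfg)
    assert frames.shape == (5, 20, 20)
    assert (frames == 150).all()
    assert not gt.masks.any()
    assert all(len(objs) == 0 for objs in gt.objects)


def test_same_seed_regenerates_bit_identical_sequence():
    cfg = dict(frame_shape=(32, 32), n_frames=8, noise_sigma=3.0, seed=11,
               particles=[ParticleSpec(start_position=(10.0, 10.0), jitter_sigma=0.5)],
               bubbles=[BubbleSpec(start_position=(25.0, 16.0), wobble_sigma=0.5)])
    f1, g1 = generate_sequence(SceneConfig(**cfg))
    f2, g2 = generate_sequence(SceneConfig(**cfg))
    assert (f1 == f2).all()
    assert (g1.masks == g2.masks).all()
    assert g1.to_json() == g2.to_json()


def test_three_separated_specks_give_three_connected_components():
    cfg = SceneConfig(
        frame_shape=(64, 64), n_frames=6, noise_sigma=0.0, seed=0,
        particles=[
            ParticleSpec("speck", size=3, start_position=(12.0, 12.0), velocity=(0.5, 0.5)),
            ParticleSpec("speck", size=3, start_position=(32.0, 40.0), velocity=(0.5, -0.5)),
            ParticleSpec("speck", size=3, start_position=(50.0, 20.0), velocity=(-0.5, 0.5)),
        ])
    _, gt = generate_sequence(cfg)
    for t in range(6):
        # independent flood-fill oracle (scipy label, 8-connectivity)
        _, n = ndimage.label(gt.masks[t], structure=np.ones((3, 3)))
        assert n == 3


def test_invalid_configs_raise():
    with pytest.raises(ConfigurationError):
        generate_sequence(SceneConfig(frame_shape=(8, 20), n_frames=5))
    with pytest.raises(ConfigurationError):
        generate_sequence(SceneConfig(frame_shape=(32, 32), n_frames=1))
    with pytest.raises(ConfigurationError):
        generate_sequence(SceneConfig(frame_shape=(32, 32), n_frames=5, noise_sigma=-1))


class TestRenderObject:
    def test_size_one_dark_speck_paints_exactly_one_darker_pixel(self):
        frame = np.full((20, 20), 200.0)
        rr, cc = render_object(ParticleSpec("speck", "dark", size=1), (7, 9), frame,
                               background_level=200)
        assert len(rr) == 1 and rr[0] == 7 and cc[0] == 9
        assert frame[7, 9] < 200
        assert (frame != 200).sum() == 1

    def test_horizontal_hair_support_is_length_wide_and_at_most_two_tall(self):
        frame = np.full((30, 30), 200.0)
        L = 9
        rr, cc = render_object(
            ParticleSpec("hair", "dark", size=L, orientation_deg=0.0), (15, 15), frame,
            background_level=200)
        assert cc.max() - cc.min() + 1 == L
        assert rr.max() - rr.min() + 1 <= 2

    def test_bubble_rim_brightness_adds_to_background(self):
        frame = np.full((30, 30), 100.0)
        rr, cc = render_object(BubbleSpec(radius=6, rim_brightness=80.0), (15, 15), frame,
                               background_level=100)
        assert frame[rr, cc].max() == 180
        # rim brighter than interior: the centre stays at background level
        assert frame[15, 15] == 100

    def test_border_clipping_is_silent(self):
        frame = np.full((20, 20), 128.0)
        rr, cc = render_object(ParticleSpec("speck", size=5), (0, 0), frame,
                               background_level=128)
        assert rr.size > 0
        assert rr.min() >= 0 and cc.min() >= 0


class TestIlluminationStep:
    def test_zero_offset_is_identity(self):
        frames = np.random.default_rng(0).integers(0, 255, (4, 10, 10)).astype(np.uint8)
        assert (illumination_step(frames, [(2, 0.0)]) == frames).all()

    def test_offset_shifts_mean_from_scheduled_frame_onward(self):
        frames = np.full((20, 16, 16), 150, dtype=np.uint8)
        out = illumination_step(frames, [(10, -30.0)])
        assert out[:10].mean() == 150
        assert out[9].mean() - out[10].mean() == pytest.approx(30.0)

    def test_two_offsets_compose_additively(self):
        frames = np.full((6, 8, 8), 100, dtype=np.uint8)
        both = illumination_step(frames, [(2, 10.0), (4, 15.0)])
        assert both[1].mean() == 100
        assert both[3].mean() == 110
        assert both[5].mean() == 125


def test_stains_are_static_excluded_from_ground_truth():
    cfg = SceneConfig(frame_shape=(40, 40), n_frames=6, noise_sigma=0.0, seed=2,
                      stains=[StainSpec(position=(20, 20), size=5, intensity_offset=-40)],
                      particles=[ParticleSpec(start_position=(8.0, 8.0), velocity=(1.0, 1.0))])
    frames, gt = generate_sequence(cfg)
    stain_region = frames[:, 18:23, 18:23]
    assert (stain_region == stain_region[0]).all()  # pixel-exact across frames
    assert not gt.masks[:, 20, 20].any()
    assert (frames[0, 20, 20] < cfg.background_level)


def test_masks_match_frame_shape_and_boxes_are_tight():
    cfg = SceneConfig(frame_shape=(32, 48), n_frames=4, seed=5,
                      particles=[ParticleSpec(size=4, start_position=(16.0, 24.0))])
    frames, gt = generate_sequence(cfg)
    assert gt.masks.shape == frames.shape
    for t in range(4):
        for rec in gt.objects[t]:
            r0, r1, c0, c1 = rec.box
            sub = gt.masks[t, r0:r1, c0:c1]
            assert sub[0].any() and sub[-1].any()
            assert sub[:, 0].any() and sub[:, -1].any()


def test_ground_truth_json_roundtrip():
    cfg = SceneConfig(frame_shape=(24, 24), n_frames=3, seed=9,
                      particles=[ParticleSpec(start_position=(12.0, 12.0))])
    _, gt = generate_sequence(cfg)
    gt2 = GroundTruth.from_json(gt.to_json())
    assert (gt.masks == gt2.masks).all()
    assert gt.objects[1][0].box == gt2.objects[1][0].box


def test_write_and_read_sequence_roundtrip(tmp_path):
    cfg = SceneConfig(frame_shape=(24, 24), n_frames=3, noise_sigma=2.0, seed=4)
    frames, gt = generate_sequence(cfg)
    write_sequence(frames, tmp_path, gt)
    back = read_sequence(tmp_path)
    assert (back == frames).all()
    assert (tmp_path / "ground_truth.json").exists()
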