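"""Unit behaviour of the adaptive mixture: matching, updates, add/merge/prune."""

import numpy as np
import pytest

from bottleinspect.gmm import (
    AdaptiveGMMBackgroundSubtractor,
    DetectionBox,
    GaussianComponent,
    GMMParams,
    PixelMixture,
    add_component,
    extract_boxes,
    fuse,
    match,
    merge_components,
    prune_components,
    select_background,
    update_learning_rate,
    update_matched,
    update_weights,
)


@pytest.fixture
def params():
    return GMMParams()


class TestInit:
    def test_constant_init_clamps_variance(self, params):
        frames = np.full((5, 4, 4), 120, dtype=np.uint8)
        bg = AdaptiveGMMBackgroundSubtractor(params).fit(frames)
        assert (bg.means_[..., 0] == 120).all()
        assert (bg.variances_[..., 0] == params.sigma2_min).all()
        assert (bg.weights_[..., 0] == 1.0).all()
        assert (bg.n_components_ == 1).all()

    def test_two_frame_population_moments(self, params):
        frames = np.stack([np.full((2, 2), 98.0), np.full((2, 2), 102.0)])
        bg = AdaptiveGMMBackgroundSubtractor(params).fit(frames)
        assert (bg.means_[..., 0] == 100.0).all()
        assert (bg.variances_[..., 0] == 4.0).all()  # population variance, 1/N

    def test_g_counter_initialised_to_half_m(self, params):
        bg = AdaptiveGMMBackgroundSubtractor(params).fit(np.zeros((2, 3, 3)))
        assert (bg.G_ == 0.5 * params.m).all()

    def test_empty_input_rejected(self, params):
        with pytest.raises(ValueError):
            AdaptiveGMMBackgroundSubtractor(params).fit(np.zeros((0, 3, 3)))


class TestMatch:
    def test_exact_mean_always_matches(self):
        assert match(GaussianComponent(1.0, 100.0, 25.0), 100.0, D=2.5)

    @pytest.mark.parametrize("x,expected", [(110.0, True), (113.0, False)])
    def test_band_edges(self, x, expected):
        comp = GaussianComponent(1.0, 100.0, 25.0)  # delta = 5
        assert match(comp, x, D=2.5) is expected  # band is +/- 12.5


class TestLearningRate:
    def test_half_m_gives_base_rate(self, params):
        params.adapt_learning_rate = False
        _, a = update_learning_rate(params.m / 2, False, params)
        assert a == params.alpha_base

    def test_endpoints(self, params):
        # G' = 0 -> 0; G' = m -> 2 alpha_base
        g, a = update_learning_rate(1.0 / params.beta_G, False, params)
        assert g == 0.0 and a == 0.0
        g, a = update_learning_rate(params.m, True, params)
        assert g == params.m and a == 2 * params.alpha_base

    def test_motion_increments_and_background_decays(self, params):
        g_up, _ = update_learning_rate(10.0, True, params)
        g_dn, _ = update_learning_rate(10.0, False, params)
        assert g_up == 11.0
        assert g_dn == pytest.approx(10.0 - 1.0 / params.beta_G)


class TestWeightUpdate:
    def test_zero_alpha_is_identity(self):
        mix = PixelMixture([GaussianComponent(0.7, 0, 4), GaussianComponent(0.3, 9, 4)])
        update_weights(mix, 0, 0.0)
        assert [c.weight for c in mix.components] == [0.7, 0.3]

    def test_matched_and_unmatched_pre_normalisation(self):
        mix = PixelMixture([GaussianComponent(0.5, 0, 4)])
        update_weights(mix, 0, 0.1, normalize=False)
        assert mix.components[0].weight == pytest.approx(0.55)
        mix = PixelMixture([GaussianComponent(0.5, 0, 4)])
        update_weights(mix, None, 0.1, normalize=False)
        assert mix.components[0].weight == pytest.approx(0.45)


class TestMatchedUpdate:
    def test_mean_is_fixed_point_and_variance_shrinks(self, params):
        comp = GaussianComponent(0.8, 100.0, 36.0)
        update_matched(comp, 100.0, 0.5, params)
        assert comp.mean == 100.0
        assert params.sigma2_min <= comp.variance < 36.0
        assert comp.unmatched_streak == 0

    def test_rho_half_moves_mean_halfway(self, params):
        params.rho_mode = "classic"
        comp = GaussianComponent(0.5, 100.0, 25.0)
        update_matched(comp, 104.0, 0.25, params)  # rho = 0.25/0.5 = 0.5
        assert comp.mean == pytest.approx(102.0)

    def test_rho_one_jumps_to_observation(self, params):
        params.rho_mode = "classic"
        comp = GaussianComponent(0.3, 100.0, 25.0)
        update_matched(comp, 140.0, 1.0, params)  # rho clamps to 1
        assert comp.mean == 140.0


class TestAddComponent:
    def test_new_component_seeded_from_lowest_ranked(self):
        params = GMMParams(beta_new=0.2)
        mix = PixelMixture([GaussianComponent(0.90, 100.0, 9.0),
                            GaussianComponent(0.10, 140.0, 25.0)])
        add_component(mix, 57.0, params)  # beta_new = 0.2
        new = mix.components[-1]
        assert new.mean == 57.0
        assert new.variance == pytest.approx(30.0)   # (1 + 0.2) * 25
        # weight 0.10 * (1 - 0.2) = 0.08 before normalisation
        total = 0.90 + 0.10 + 0.08
        assert new.weight == pytest.approx(0.08 / total)
        assert sum(c.weight for c in mix.components) == pytest.approx(1.0)

    def test_replacement_at_k_max_keeps_count(self, params):
        comps = [GaussianComponent(w, 10.0 * i, 9.0) for i, w in
                 enumerate([0.4, 0.3, 0.15, 0.1, 0.05])]
        mix = PixelMixture(list(comps))
        add_component(mix, 200.0, params)
        assert len(mix.components) == params.K_max
        assert mix.components[-1].mean == 200.0
        assert mix.components[-1].variance == params.sigma2_init


class TestMerge:
    def test_equal_weights_symmetric_mean(self):
        c = merge_components(GaussianComponent(0.3, 100.0, 4.0),
                             GaussianComponent(0.3, 104.0, 4.0))
        assert c.mean == pytest.approx(102.0)
        assert c.weight == pytest.approx(0.6)

    def test_worked_example(self):
        # independent hand evaluation: w=0.8, mu=(0.6*100+0.2*104)/0.8=101,
        # var=(0.6*4+0.2*16)/0.8=7
        c = merge_components(GaussianComponent(0.6, 100.0, 4.0, 3),
                             GaussianComponent(0.2, 104.0, 16.0, 7))
        assert (c.weight, c.mean, c.variance) == pytest.approx((0.8, 101.0, 7.0))
        assert c.unmatched_streak == 3  # min of the two

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValueError):
            merge_components(GaussianComponent(0.0, 1, 4), GaussianComponent(0.0, 2, 4))


class TestPrune:
    def test_recently_matched_components_survive(self, params):
        mix = PixelMixture([GaussianComponent(0.6, 0, 4, 0), GaussianComponent(0.4, 9, 4, 0)])
        prune_components(mix, params)
        assert len(mix.components) == 2

    def test_stale_component_removed_and_weights_renormalised(self, params):
        mix = PixelMixture([GaussianComponent(0.5, 0, 4, 0),
                            GaussianComponent(0.3, 9, 4, 0),
                            GaussianComponent(0.2, 20, 4, int(params.V_max) + 1)])
        prune_components(mix, params)
        assert len(mix.components) == 2
        assert sum(c.weight for c in mix.components) == pytest.approx(1.0)

    def test_never_prunes_below_k_min(self, params):
        mix = PixelMixture([GaussianComponent(1.0, 0, 4, int(params.V_max) + 10)])
        prune_components(mix, params)
        assert len(mix.components) == params.K_min


class TestSelectBackground:
    @pytest.mark.parametrize("T_b,expected", [(0.7, 2), (0.95, 3)])
    def test_cumulative_weight_counts(self, T_b, expected):
        mix = PixelMixture([GaussianComponent(0.5, 0, 4), GaussianComponent(0.3, 9, 4),
                            GaussianComponent(0.2, 20, 4)])
        assert select_background(mix, T_b) == expected

    def test_single_component_is_always_background(self):
        assert select_background(PixelMixture([GaussianComponent(1.0, 0, 4)]), 0.9) == 1


class TestStepAndBackgroundImage:
    def test_static_sequence_has_empty_foreground(self, params):
        frames = np.full((30, 8, 8), 90, dtype=np.uint8)
        bg = AdaptiveGMMBackgroundSubtractor(params).fit(frames[:5])
        for t in range(5, 30):
            fg = bg.step(frames[t], np.zeros((8, 8), bool))
            assert not fg.any()

    def test_background_image_matches_static_scene(self, params):
        scene = np.tile(np.linspace(40, 200, 8, dtype=np.uint8), (8, 1))
        bg = AdaptiveGMMBackgroundSubtractor(params).fit(np.stack([scene] * 3))
        img = bg.background_image()
        assert np.abs(img.astype(int) - scene.astype(int)).max() <= 1
        assert img.dtype == np.uint8

    def test_shape_mismatch_rejected(self, params):
        bg = AdaptiveGMMBackgroundSubtractor(params).fit(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError):
            bg.step(np.zeros((5, 5)))

    def test_moving_square_recalled_after_warmup(self, params):
        rng = np.random.default_rng(0)
        frames = []
        truth = []
        for t in range(30):
            f = np.full((40, 40), 180.0)
            r = 2 + 2 * t
            mask = np.zeros((40, 40), bool)
            if r + 5 <= 38:
                f[r:r + 5, 10:15] = 60.0
                mask[r:r + 5, 10:15] = True
            frames.append(np.clip(f + rng.normal(0, 1, f.shape), 0, 255).astype(np.uint8))
            truth.append(mask)
        bg = AdaptiveGMMBackgroundSubtractor(params).fit(np.stack(frames[:3]))
        for t in range(3, 15):
            fg = bg.step(frames[t])
            if t >= 6 and truth[t].any():
                recall = (fg & truth[t]).sum() / truth[t].sum()
                assert recall > 0.9

    def test_stopped_object_absorbed_into_background(self):
        params = GMMParams(alpha_base=0.05)
        frames = [np.full((16, 16), 180, dtype=np.uint8) for _ in range(3)]
        bg = AdaptiveGMMBackgroundSubtractor(params).fit(np.stack(frames))
        still = np.full((16, 16), 180, dtype=np.uint8)
        still[6:10, 6:10] = 60
        flagged_at_first = None
        empty_after = None
        for t in range(80):
            fg = bg.step(still)
            if flagged_at_first is None:
                flagged_at_first = fg[6:10, 6:10].any()
            if fg[6:10, 6:10].sum() == 0:
                empty_after = t
                break
        assert flagged_at_first
        assert empty_after is not None and empty_after < 60


class TestFuse:
    def test_and_with_empty_motion_is_empty(self):
        fg = np.ones((10, 10), bool)
        assert not fuse(fg, np.zeros((10, 10), bool), mode="and").any()

    def test_identical_blob_preserved(self):
        blob = np.zeros((20, 20), bool)
        blob[5:12, 5:12] = True
        fused = fuse(blob, blob, close_kernel=3, mode="and")
        assert (fused & blob).sum() == blob.sum()

    def test_or_keeps_disjoint_blobs(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[2:5, 2:5] = True
        b[14:17, 14:17] = True
        fused = fuse(a, b, close_kernel=1, mode="or")
        assert fused[3, 3] and fused[15, 15]

    def test_motion_closing_fills_hole_between_bands(self):
        # leading + trailing bands of a uniform mover enclose its interior
        fg = np.zeros((20, 20), bool)
        fg[8:12, 6:12] = True                # mixture sees the full body
        motion = np.zeros((20, 20), bool)
        motion[8:12, 6:8] = True             # trailing edge band
        motion[8:12, 10:12] = True           # leading edge band
        fused = fuse(fg, motion, close_kernel=3, mode="and")
        assert fused[8:12, 6:12].all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestExtractBoxes:
    def test_empty_mask(self):
        assert extract_boxes(np.zeros((10, 10), bool)) == []

    def test_filled_rectangle_box_and_area(self):
        mask = np.zeros((8, 8), bool)
        mask[2:5, 1:5] = True
        boxes = extract_boxes(mask, min_area=4, frame_index=7)
        assert boxes == [DetectionBox(7, 2, 5, 1, 5, 12)]

    def test_min_area_filters_small_blob(self):
        mask = np.zeros((12, 12), bool)
        mask[1:4, 1:4] = True   # area 9
        mask[8, 8] = True       # area 1
        boxes = extract_boxes(mask, min_area=4)
        assert len(boxes) == 1
        assert boxes[0].area == 9

    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((6, 6), bool)
        mask[1, 1] = mask[2, 2] = mask[3, 3] = True  # 8-connected
        boxes = extract_boxes(mask, min_area=1)
        assert len(boxes) == 1
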