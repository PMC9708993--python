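"""SSIM and adversarial losses, network contracts, ROI geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ggnforge.gan import (
    GANConfig,
    LossBreakdown,
    adversarial_loss,
    build_discriminator,
    build_generator,
    composite,
    crop_roi,
    discriminator_loss,
    ssim,
    ssim_loss,
    total_generator_loss,
)
from ggnforge import nn


def _rand_image(seed, n=8):
    return np.random.default_rng(seed).uniform(0, 1, (n, n))


class TestSSIM:
    def test_identical_images_give_one(self):
        x = _rand_image(0)
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)
        assert ssim_loss(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_constant_images_equal_means(self):
        x = np.full((4, 4), 0.3)
        assert ssim(x, x.copy()) == pytest.approx(1.0)

    def test_anticorrelated_2x2_matches_hand_evaluation(self):
        x = np.array([[0.0, 1.0], [0.0, 1.0]])
        y = np.array([[1.0, 0.0], [1.0, 0.0]])
        c1, c2 = 1e-4, 9e-4
        # direct arithmetic: mu both 0.5, var both 0.25, cov -0.25
        expected = ((2 * 0.5 * 0.5 + c1) * (2 * -0.25 + c2)) / (
            (0.25 + 0.25 + c1) * (0.25 + 0.25 + c2))
        assert ssim(x, y, c1=c1, c2=c2) == pytest.approx(expected, rel=1e-12)
        assert ssim_loss(x, y, c1=c1, c2=c2) == pytest.approx(1 - expected, rel=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetry_and_unit_self_similarity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, (6, 6))
        y = rng.uniform(0, 1, (6, 6))
        assert ssim(x, y) == pytest.approx(ssim(y, x), rel=1e-9)
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-9)
        assert -1.0 - 1e-9 <= ssim(x, y) <= 1.0 + 1e-9

    def test_monotone_degradation_under_noise(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.2, 0.8, (32, 32))
        values = []
        for amp in [0.0, 0.05, 0.1, 0.2, 0.4]:
            vals = [ssim(x, x + np.random.default_rng(s).normal(0, amp, x.shape))
                    for s in range(10)]
            values.append(np.mean(vals))
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_windowed_mode_agrees_on_identical_images(self):
        x = _rand_image(3, n=16)
        assert ssim(x, x, mode="windowed") == pytest.approx(1.0, abs=1e-5)

    def test_printed_form_differs_and_is_not_unital(self):
        x = _rand_image(1)
        assert ssim(x, x, printed_form=True) != pytest.approx(1.0, abs=1e-3)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((2, 2)), np.zeros((3, 3)))


class TestAdversarialLosses:
    def test_half_score_closed_form(self):
        assert adversarial_loss([0.5]) == pytest.approx(math.log(2), rel=1e-12)

    def test_sum_matches_brute_force(self):
        assert adversarial_loss([0.5, 0.25]) == pytest.approx(
            math.log(2) + math.log(4), rel=1e-12)
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.uniform(1e-4, 1 - 1e-4, size=rng.integers(1, 8))
            oracle = sum(-math.log(s) for s in scores)
            assert adversarial_loss(scores) == pytest.approx(oracle, rel=1e-10)

    def test_limit_to_zero_as_scores_approach_one(self):
        assert adversarial_loss([1 - 1e-12]) < 1e-9

    def test_domain_errors(self):
        for bad in ([0.0], [1.0], [-0.1], [1.2]):
            with pytest.raises(ValueError):
                adversarial_loss(bad)

    def test_discriminator_loss_closed_forms(self):
        assert discriminator_loss([1 - 1e-12], [1e-12]) < 1e-9
        assert discriminator_loss([0.5], [0.5]) == pytest.approx(
            2 * math.log(2), rel=1e-12)
        rng = np.random.default_rng(1)
        real = rng.uniform(0.01, 0.99, 5)
        fake = rng.uniform(0.01, 0.99, 3)
        oracle = sum(-math.log(r) for r in real) + sum(
            -math.log(1 - f) for f in fake)
        assert discriminator_loss(real, fake) == pytest.approx(oracle, rel=1e-10)


class TestTotalGeneratorLoss:
    def test_perfect_generator_limit(self):
        x = _rand_image(0, 16)
        bd = total_generator_loss(x, x, (4, 4, 12, 12), 1 - 1e-12, 1 - 1e-12)
        assert bd.total == pytest.approx(0.0, abs=1e-9)

    def test_total_is_exact_sum_of_parts(self):
        x, y = _rand_image(1, 16), _rand_image(2, 16)
        bd = total_generator_loss(x, y, (4, 4, 12, 12), 0.3, 0.7)
        assert bd.total == pytest.approx(
            bd.l_ssim_whole + bd.l_adv_whole + bd.l_ssim_roi + bd.l_adv_roi,
            abs=1e-12)
        assert bd.total >= max(bd.l_ssim_whole, bd.l_adv_whole,
                               bd.l_ssim_roi, bd.l_adv_roi)

    def test_composition_of_closed_forms(self):
        x, y = _rand_image(3, 8), _rand_image(4, 8)
        box = (2, 2, 6, 6)
        bd = total_generator_loss(x, y, box, 0.5, 0.5)
        expected = (ssim_loss(x, y) + ssim_loss(x[2:6, 2:6], y[2:6, 2:6])
                    + 2 * math.log(2))
        assert bd.total == pytest.approx(expected, rel=1e-10)


class TestGeometry:
    def test_crop_identity(self):
        x = _rand_image(0, 2)
        np.testing.assert_array_equal(crop_roi(x, (0, 0, 2, 2)), x)

    def test_crop_center_of_toy_grid(self):
        grid = np.arange(16.0).reshape(4, 4)
        np.testing.assert_array_equal(crop_roi(grid, (1, 1, 3, 3)),
                                      [[5.0, 6.0], [9.0, 10.0]])

    def test_crop_paste_round_trip(self):
        x = _rand_image(5, 8)
        box = (2, 3, 6, 7)
        y = x.copy()
        y[2:6, 3:7] = crop_roi(x, box)
        np.testing.assert_array_equal(y, x)

    def test_out_of_bounds_crop_raises(self):
        with pytest.raises(ValueError):
            crop_roi(np.zeros((4, 4)), (1, 1, 5, 5))

    def test_composite_select(self):
        gen, inp = _rand_image(6, 4), _rand_image(7, 4)
        mask = np.zeros((4, 4), dtype=bool)
        np.testing.assert_array_equal(composite(gen, inp, mask), inp)
        np.testing.assert_array_equal(composite(gen, inp, ~mask), gen)
        mask[1:3, 1:3] = True
        out = composite(gen, inp, mask)
        for r in range(4):
            for c in range(4):
                assert out[r, c] == (gen if mask[r, c] else inp)[r, c]


class TestNetworkContracts:
    @pytest.mark.parametrize("size", [32, 64])
    def test_generator_shape_and_range(self, size):
        config = GANConfig(image_size=size, roi_size=size // 4,
                           n_res_blocks=2, base_channels=4)
        gen = build_generator(config)
        x = nn.Tensor(np.zeros((1, 1, size, size), dtype=np.float32))
        out = gen(x)
        assert out.data.shape == (1, 1, size, size)
        assert (out.data >= 0).all() and (out.data <= 1).all()

    def test_generator_inference_deterministic(self):
        config = GANConfig(image_size=32, roi_size=8, n_res_blocks=2,
                           base_channels=4, seed=5)
        gen = build_generator(config)
        gen.eval()
        x = nn.Tensor(np.random.default_rng(0).uniform(size=(1, 1, 32, 32)))
        np.testing.assert_array_equal(gen(x).data, gen(x).data)

    def test_discriminator_score_contract(self):
        config = GANConfig(image_size=64, roi_size=32, n_res_blocks=1,
                           base_channels=4)
        d_roi = build_discriminator(config, "roi")
        x = nn.Tensor(np.random.default_rng(1).uniform(size=(3, 1, 32, 32)))
        s = d_roi(x).data
        assert s.shape == (3, 1)
        assert np.isfinite(s).all()
        assert (s > 0).all() and (s < 1).all()

    def test_whole_discriminator_rejects_roi_sized_input(self):
        config = GANConfig(image_size=64, roi_size=32, n_res_blocks=1,
                           base_channels=4)
        d = build_discriminator(config, "whole")
        with pytest.raises(ValueError):
            d(nn.Tensor(np.zeros((1, 1, 32, 32), dtype=np.float32)))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GANConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            GANConfig(image_size=32, roi_size=64)


class TestLossBreakdown:
    def test_sum_invariant_bitwise(self):
        bd = LossBreakdown(0.1, 0.2, 0.3, 0.4)
        assert bd.total == 0.1 + 0.2 + 0.3 + 0.4
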