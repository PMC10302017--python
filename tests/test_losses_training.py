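"""Loss formulas, adversarial mechanics, and the training loops."""

import numpy as np
import pytest

from dwisr.losses import (
    LossWeights,
    clip_weights,
    deblur_loss,
    denoise_losses,
    sr_losses,
    wasserstein_losses,
    wgan_gp_d_loss,
)
from dwisr.networks import FeatureExtractor, NetSpec, build_denoise_gan
from dwisr.nn import Tensor
from dwisr.training import TrainConfig, denoise_volume_stream, train_adversarial


class _LinearCritic:
    """D(x) = <w, x> with configurable norm; exactly 1-Lipschitz at norm 1."""

    def __init__(self, shape, scale=1.0, seed=0):
        w = np.random.default_rng(seed).normal(size=shape)
        self.w = Tensor(scale * w / np.linalg.norm(w))

    def __call__(self, x):
        from dwisr.nn.autograd import reshape, sum_

        n = x.shape[0]
        flat = reshape(x, (n, -1))
        wf = reshape(self.w, (-1, 1))
        return flat @ wf


class TestWasserstein:
    def test_equal_batches_give_zero(self):
        d, _ = wasserstein_losses(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert d.item() == 0.0

    def test_printed_arithmetic(self):
        d, g = wasserstein_losses(np.array([1.0, 1.0]), np.array([0.0, 0.0]))
        assert d.item() == -1.0
        assert g.item() == 0.0  # -mean(fake)

    def test_translation_invariance(self, rng):
        real = rng.normal(size=10)
        fake = rng.normal(size=10)
        d1, _ = wasserstein_losses(real, fake)
        d2, _ = wasserstein_losses(real + 7.3, fake + 7.3)
        assert d1.item() == pytest.approx(d2.item(), abs=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_losses(np.array([]), np.array([1.0]))


class TestClipWeights:
    def test_all_parameters_bounded_by_c(self):
        g, d = build_denoise_gan(NetSpec(role="denoise_disc", width_multiplier=0.25))
        for p in d.parameters():
            p.data = p.data + 5.0
        clip_weights(d, 0.01)
        assert max(np.abs(p.data).max() for p in d.parameters()) <= 0.01

    def test_within_range_unchanged(self):
        g, d = build_denoise_gan(NetSpec(role="denoise_disc", width_multiplier=0.25))
        before = [p.data.copy() * 0.001 for p in d.parameters()]
        for p, b in zip(d.parameters(), before):
            p.data = b.copy()
        clip_weights(d, 0.01)
        assert all(np.array_equal(p.data, b) for p, b in zip(d.parameters(), before))

    def test_saturation_exact(self):
        g, d = build_denoise_gan(NetSpec(role="denoise_disc", width_multiplier=0.25))
        d.parameters()[0].data[:] = 5.0
        clip_weights(d, 0.01)
        assert np.all(d.parameters()[0].data == 0.01)


class TestSRLosses:
    def test_perfect_reconstruction_zeroes_mse_and_rlt(self, rng):
        hr = rng.random((1, 1, 8, 8))
        br = sr_losses(hr, hr, registered_neighbors=[hr], target_frame=hr)
        assert br.component_values()["mse"] == 0.0
        assert br.component_values()["rlt"] == 0.0

    def test_unit_difference_gives_unit_mse(self):
        hr = np.zeros((2, 2))
        sr = np.ones((2, 2))
        br = sr_losses(sr, hr)
        assert br.component_values()["mse"] == 1.0

    def test_total_is_weighted_component_sum(self, rng):
        w = LossWeights()
        hr = rng.random((1, 1, 8, 8))
        sr = rng.random((1, 1, 8, 8))
        critic = _LinearCritic((64,))
        nb = [rng.random((1, 1, 8, 8)) for _ in range(2)]
        br = sr_losses(sr, hr, critic=critic, registered_neighbors=nb,
                       target_frame=hr, weights=w)
        vals = br.component_values()
        expect = vals["mse"] + w.adv_weight * vals["adversarial"] + w.rlt_weight * vals["rlt"]
        assert br.total_value() == pytest.approx(expect, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sr_losses(np.zeros((4, 4)), np.zeros((8, 8)))


class TestDeblurLoss:
    def test_perfect_output_leaves_only_adversarial(self, rng):
        x = rng.random((1, 1, 16, 16))
        critic = _LinearCritic((256,))
        fx = FeatureExtractor(seed=0)
        br = deblur_loss(x, x.copy(), critic, fx)
        assert br.component_values()["content"] == 0.0
        assert br.total_value() == pytest.approx(br.component_values()["adversarial"])

    def test_lambda_zero_is_pure_adversarial(self, rng):
        w = LossWeights(deblur_lambda=0.0)
        a, b = rng.random((1, 1, 16, 16)), rng.random((1, 1, 16, 16))
        critic = _LinearCritic((256,))
        br = deblur_loss(a, b, critic, FeatureExtractor(seed=0), weights=w)
        assert br.total_value() == pytest.approx(br.component_values()["adversarial"],
                                                 abs=1e-12)

    def test_identity_extractor_content_equals_pixel_mse(self, rng):
        a, b = rng.random((1, 1, 16, 16)), rng.random((1, 1, 16, 16))
        critic = _LinearCritic((256,))
        br = deblur_loss(a, b, critic, FeatureExtractor(kind="identity"))
        assert br.component_values()["content"] == pytest.approx(
            ((a - b) ** 2).mean(), rel=1e-6
        )


class TestGradientPenalty:
    def test_unit_norm_linear_critic_has_zero_penalty(self, rng):
        critic = _LinearCritic((4, 4, 4), scale=1.0)
        real = rng.random((3, 1, 4, 4, 4)).reshape(3, -1).reshape(3, 4, 4, 4)
        fake = rng.random((3, 4, 4, 4))
        _, pen = wgan_gp_d_loss(critic, real, fake, psi=10.0, seed=0)
        assert abs(pen.item()) < 1e-12

    def test_double_norm_critic_penalty_is_one(self, rng):
        critic = _LinearCritic((4, 4, 4), scale=2.0)
        real = rng.random((3, 4, 4, 4))
        fake = rng.random((3, 4, 4, 4))
        loss, pen = wgan_gp_d_loss(critic, real, fake, psi=10.0, seed=0)
        assert pen.item() == pytest.approx(1.0, abs=1e-9)

    def test_interpolation_endpoints(self, rng):
        real = rng.random((2, 4, 4))
        fake = rng.random((2, 4, 4))
        for eps, expect in [(0.0, fake), (1.0, real)]:
            xhat = eps * real + (1 - eps) * fake
            assert np.allclose(xhat, expect)

    def test_shape_mismatch_rejected(self, rng):
        critic = _LinearCritic((4, 4))
        with pytest.raises(ValueError):
            wgan_gp_d_loss(critic, rng.random((2, 4, 4)), rng.random((3, 4, 4)))


class TestDenoiseLosses:
    def test_perfect_output_zeroes_mse_and_perceptual(self, rng):
        x = rng.random((1, 1, 8, 8, 8))
        br = denoise_losses(x, x.copy(), extractor=FeatureExtractor(seed=0))
        assert br.component_values()["mse"] == 0.0
        assert br.component_values()["perceptual"] == 0.0

    def test_difference_of_two_gives_mse_four(self):
        a = np.zeros((2, 2, 2))
        b = np.full((2, 2, 2), 2.0)
        br = denoise_losses(b, a)
        assert br.component_values()["mse"] == 4.0

    def test_total_is_weighted_component_sum(self, rng):
        w = LossWeights(denoise_deltas=(1.0, 0.1, 1e-3))
        x = rng.random((2, 1, 8, 8, 8))
        y = rng.random((2, 1, 8, 8, 8))
        critic = _LinearCritic((512,))
        br = denoise_losses(x, y, critic=critic, extractor=FeatureExtractor(seed=0),
                            weights=w)
        vals = br.component_values()
        expect = (1.0 * vals["mse"] + 0.1 * vals["perceptual"]
                  + 1e-3 * vals["adversarial"])
        assert br.total_value() == pytest.approx(expect, abs=1e-12)


class TestTrainingLoop:
    def test_zero_steps_leaves_generator_untouched(self):
        G, D = build_denoise_gan(NetSpec(role="denoise_gen", width_multiplier=0.25, seed=0))
        before = [p.data.copy() for p in G.parameters()]
        cfg = TrainConfig(steps=0, seed=0, gan_mode="wgan_gp")
        pair = train_adversarial(G, D, denoise_volume_stream(),
                                 lambda o, t, d: denoise_losses(o, t, critic=d), cfg)
        assert pair.history == []
        assert all(np.array_equal(p.data, b) for p, b in zip(G.parameters(), before))

    def test_same_seed_gives_identical_history(self):
        def run():
            G, D = build_denoise_gan(NetSpec(role="denoise_gen", width_multiplier=0.25,
                                             seed=1))
            cfg = TrainConfig(learning_rate=1e-3, steps=3, seed=4, gan_mode="wgan_gp",
                              batch_size=1)
            return train_adversarial(
                G, D, denoise_volume_stream(shape=(8, 8, 8)),
                lambda o, t, d: denoise_losses(o, t, critic=d), cfg
            ).history

        assert run() == run()

    def test_clipping_mode_keeps_critic_bounded_every_step(self):
        G, D = build_denoise_gan(NetSpec(role="denoise_gen", width_multiplier=0.25, seed=2))
        cfg = TrainConfig(learning_rate=1e-3, steps=2, seed=0, gan_mode="wgan_clip",
                          critic_updates_per_gen=2, batch_size=1)
        train_adversarial(G, D, denoise_volume_stream(shape=(8, 8, 8)),
                          lambda o, t, d: denoise_losses(o, t, critic=d), cfg)
        assert max(np.abs(p.data).max() for p in D.parameters()) <= 0.01

    def test_generator_loss_improves_over_short_run(self):
        G, D = build_denoise_gan(NetSpec(role="denoise_gen", width_multiplier=0.25, seed=3))
        cfg = TrainConfig(learning_rate=1e-3, steps=20, seed=3, gan_mode="wgan_gp",
                          batch_size=1)
        pair = train_adversarial(G, D, denoise_volume_stream(shape=(8, 8, 8)),
                                 lambda o, t, d: denoise_losses(o, t, critic=d), cfg)
        totals = [h["g_total"] for h in pair.history]
        assert np.mean(totals[-10:]) < np.mean(totals[:10])
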