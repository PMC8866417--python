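"""Ambient training mechanics: schedules, channels, degeneracy to the plain
GAN, gradient flow through the operator insertion, and reproducibility."""

import numpy as np
import pytest

from ambientsom import ambient_gan as ab
from ambientsom import autograd as ag
from ambientsom import imaging_operators as iop
from ambientsom import object_simulator as osim
from ambientsom.autograd import Tensor


@pytest.fixture(scope="module")
def small_specs():
    gspec = ab.GeneratorSpec(latent_dim=16, final_resolution=16, width=32)
    dspec = ab.DiscriminatorSpec(width=32)
    return gspec, dspec


@pytest.fixture(scope="module")
def small_images():
    cfg = osim.LumpyConfig(grid_size=16, normalize="per_image_minmax")
    return osim.make_ensemble(cfg, 64, seed=1).images


def short_config(**kw):
    kw.setdefault("loss", "logistic_r1")
    kw.setdefault("batch_size", 8)
    kw.setdefault("images_per_stage", 64)
    kw.setdefault("seed", 3)
    return ab.TrainingConfig(**kw)


class TestSchedule:
    def test_progressive_chain_to_final(self):
        gspec = ab.GeneratorSpec(final_resolution=32)
        plans = ab.progressive_schedule(gspec, short_config())
        assert [p.resolution for p in plans] == [4, 8, 16, 32]
        assert plans[0].fade_fraction == 0.0
        assert sum(p.images for p in plans) == 4 * 64

    def test_skip_sum_single_stage(self):
        gspec = ab.GeneratorSpec(final_resolution=32, architecture="skip_sum")
        plans = ab.progressive_schedule(gspec, short_config())
        assert plans == [ab.StagePlan(32, 64, 0.0)]

    def test_zero_fade_fraction(self):
        gspec = ab.GeneratorSpec(final_resolution=16)
        plans = ab.progressive_schedule(gspec, short_config(fade_fraction=0.0))
        assert all(p.fade_fraction == 0.0 for p in plans)

    def test_non_power_of_two_resolution_rejected(self):
        with pytest.raises(ValueError):
            ab.GeneratorSpec(final_resolution=24)


class TestChannels:
    def test_fourier_channel_zero_noise_full_mask_is_identity_map(self, rng):
        model = iop.ForwardModel(iop.make_cartesian_mask(16, 1, "full"))
        chan = ab.FourierChannel(model, iop.Reconstructor("real_part"))
        x = rng.normal(size=(3, 16, 16))
        out = chan.reconstruct_fake(Tensor(x), np.random.default_rng(0))
        assert np.abs(out.data - x).max() < 1e-12

    def test_fresh_noise_per_call(self, rng):
        model = iop.ForwardModel(iop.make_cartesian_mask(16, 1, "full"),
                                 iop.NoiseModel(1.0))
        chan = ab.FourierChannel(model, iop.Reconstructor("real_part"))
        x = Tensor(rng.normal(size=(2, 16, 16)))
        noise_rng = np.random.default_rng(0)
        a = chan.reconstruct_fake(x, noise_rng).data
        b = chan.reconstruct_fake(x, noise_rng).data
        assert not np.allclose(a, b)

    def test_corrected_magnitude_channel_matches_operator(self, rng):
        """Differentiable training channel vs the numpy operator, shared draw."""
        n = 16
        model = iop.ForwardModel(iop.make_cartesian_mask(n, 1, "full"),
                                 iop.NoiseModel(0.7))
        chan = ab.FourierChannel(model, iop.Reconstructor("corrected_magnitude"))
        f = rng.normal(size=(n, n))

        class FixedRng:
            def __init__(self, noise):
                self._n = noise

            def normal(self, scale, size):
                return self._n

        noise = iop.draw_kspace_noise(model.mask, 0.7, 5)
        unshifted = np.fft.ifftshift(noise)
        fixed = FixedRng(np.stack([unshifted.real, unshifted.imag])[:, None])
        out = chan.reconstruct_fake(Tensor(f[None]), fixed).data[0]
        ref = iop.corrected_fake_reconstruct(f, model, seed=5)
        assert np.allclose(out, ref, atol=1e-10)

    def test_corrected_magnitude_requires_full_sampling(self):
        mask = iop.make_cartesian_mask(16, 2, "uniform_random", seed=0)
        model = iop.ForwardModel(mask, iop.NoiseModel(1.0))
        with pytest.raises(ValueError):
            ab.FourierChannel(model, iop.Reconstructor("corrected_magnitude"))

    def test_gradient_flows_through_channel(self, rng):
        """Finite-difference gradient of a loss through O o H_n."""
        mask = iop.make_cartesian_mask(8, 2, "uniform_random", seed=1)
        model = iop.ForwardModel(mask, iop.NoiseModel(0.0))
        chan = ab.FourierChannel(model, iop.Reconstructor("real_part"))
        x = rng.normal(size=(1, 8, 8))
        xt = Tensor(x, requires_grad=True)
        loss = (chan.reconstruct_fake(xt, np.random.default_rng(0)) ** 2.0).sum()
        (g,) = ag.grad(loss, [xt])
        eps = 1e-6
        i = (0, 3, 5)
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        num = (float((chan.reconstruct_fake(Tensor(xp), np.random.default_rng(0))**2.0).sum().data)
               - float((chan.reconstruct_fake(Tensor(xm), np.random.default_rng(0))**2.0).sum().data)) / (2 * eps)
        assert g.data[i] == pytest.approx(num, rel=1e-5)


class TestDegeneracy:
    def test_identity_operators_reproduce_plain_gan_bitwise(self, small_specs,
                                                            small_images):
        gspec, dspec = small_specs
        cfg = short_config()
        plain = ab.train_plain_gan(small_images, gspec, dspec, cfg)
        ambient = ab.train_ambientgan(small_images, None, gspec, dspec, cfg)
        for a, b in zip(plain.generator.parameters(),
                        ambient.generator.parameters()):
            assert np.array_equal(a.data, b.data)
        assert plain.manifest["log"] == ambient.manifest["log"]

    def test_zero_noise_full_mask_fourier_matches_identity_closely(
            self, small_specs, small_images):
        gspec, dspec = small_specs
        cfg = short_config(images_per_stage=16)
        model = iop.ForwardModel(iop.make_cartesian_mask(16, 1, "full"))
        spectra = np.fft.fftshift(np.fft.fft2(small_images[:32]), axes=(1, 2))
        ambient = ab.train_ambientgan(spectra, (model, iop.Reconstructor("real_part")),
                                      gspec, dspec, cfg)
        plain = ab.train_plain_gan(small_images[:32], gspec, dspec, cfg)
        for a, b in zip(plain.generator.parameters(),
                        ambient.generator.parameters()):
            assert np.allclose(a.data, b.data, atol=1e-7)


class TestTrainingContracts:
    def test_loss_trajectory_reproducible(self, small_specs, small_images):
        gspec, dspec = small_specs
        a = ab.train_plain_gan(small_images, gspec, dspec,
                               short_config(log_every=1, images_per_stage=80))
        b = ab.train_plain_gan(small_images, gspec, dspec,
                               short_config(log_every=1, images_per_stage=80))
        assert a.manifest["log"] == b.manifest["log"]

    def test_noisy_training_data_raises_estimated_sample_noise(self, small_specs,
                                                               small_images, rng):
        from ambientsom.noise_estimation import estimate_image_noise_std

        gspec, dspec = small_specs
        cfg = short_config(images_per_stage=2000, seed=5)
        clean_model = ab.train_plain_gan(small_images, gspec, dspec, cfg)
        noisy = small_images + rng.normal(scale=0.5, size=small_images.shape)
        noisy_model = ab.train_plain_gan(noisy, gspec, dspec, cfg)
        est_clean = estimate_image_noise_std(clean_model.sample(64, 0).images).sigma
        est_noisy = estimate_image_noise_std(noisy_model.sample(64, 0).images).sigma
        assert est_noisy > est_clean

    def test_perturbing_generator_changes_discriminator_input(self, small_specs, rng):
        """Gradient-path property through the operator insertion."""
        gspec, dspec = small_specs
        gen = ab._build_generator(gspec, np.random.default_rng(0))
        mask = iop.make_cartesian_mask(16, 2, "uniform_random", seed=0)
        chan = ab.FourierChannel(iop.ForwardModel(mask),
                                 iop.Reconstructor("real_part"))
        z = Tensor(rng.normal(size=(2, 16)))
        before = chan.reconstruct_fake(
            gen.forward(z, noise_rng=None), np.random.default_rng(0)).data.copy()
        gen.net.trunk.weight.data = gen.net.trunk.weight.data + 1e-3
        after = chan.reconstruct_fake(
            gen.forward(z, noise_rng=None), np.random.default_rng(0)).data
        assert not np.allclose(before, after)

    def test_untrained_model_samples_are_finite_and_shaped(self, small_specs):
        gspec, _ = small_specs
        model = ab.GeneratorModel(
            generator=ab._build_generator(gspec, np.random.default_rng(0)),
            spec=gspec)
        ens = model.sample(10, seed=4)
        assert ens.images.shape == (10, 16, 16)
        assert np.all(np.isfinite(ens.images))

    def test_sampling_deterministic_in_seed(self, small_specs, small_images):
        gspec, dspec = small_specs
        model = ab.train_plain_gan(small_images, gspec, dspec, short_config())
        a = ab.sample_objects(model, 6, seed=9)
        b = ab.sample_objects(model, 6, seed=9)
        c = ab.sample_objects(model, 6, seed=10)
        assert np.array_equal(a.images, b.images)
        assert not np.allclose(a.images, c.images)

    def test_mismatched_data_resolution_rejected(self, small_specs, rng):
        gspec, dspec = small_specs
        with pytest.raises(ValueError):
            ab.train_plain_gan(rng.normal(size=(8, 32, 32)), gspec, dspec,
                               short_config())

    def test_checkpoint_round_trip(self, small_specs, small_images, tmp_path):
        gspec, dspec = small_specs
        model = ab.train_plain_gan(small_images, gspec, dspec, short_config())
        path = tmp_path / "model.npz"
        model.save(path)
        back = ab.GeneratorModel.load(path)
        assert np.array_equal(back.sample(4, 2).images, model.sample(4, 2).images)
        assert back.manifest["channel"] == "identity"

    def test_wgan_gp_loss_also_trains(self, small_specs, small_images):
        gspec, dspec = small_specs
        model = ab.train_plain_gan(small_images, gspec, dspec,
                                   short_config(loss="wgan_gp"))
        assert np.all(np.isfinite(model.sample(4, 0).images))
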