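"""Forward/reconstruction operator contracts: DFT oracles, masks, noise
propagation, the magnitude correction, and the measurement projector."""

import numpy as np
import pytest
from scipy import stats

from ambientsom import imaging_operators as iop


def brute_force_dft2(x):
    """Double-sum DFT oracle (non-unitary forward), O(N^4)."""
    n = x.shape[0]
    out = np.zeros((n, n), dtype=complex)
    for ky in range(n):
        for kx in range(n):
            for y in range(n):
                for xx in range(n):
                    out[ky, kx] += x[y, xx] * np.exp(-2j * np.pi * (ky * y + kx * xx) / n)
    return out


class TestMasks:
    def test_full_mask_identity(self):
        mask = iop.make_cartesian_mask(32, 1, "full")
        assert mask.acceleration == 1.0
        assert len(mask.kept_lines) == 32

    @pytest.mark.parametrize("grid,R,expected", [(256, 2, 128), (256, 4, 64),
                                                 (32, 1.25, 26), (8, 4, 2)])
    def test_kept_line_count(self, grid, R, expected):
        mask = iop.make_cartesian_mask(grid, R, "uniform_random", seed=0)
        assert len(mask.kept_lines) == expected
        assert 0 in mask.kept_lines

    def test_small_grid_mask_deterministic(self):
        a = iop.make_cartesian_mask(8, 4, "uniform_random", seed=5)
        b = iop.make_cartesian_mask(8, 4, "uniform_random", seed=5)
        assert a.kept_lines == b.kept_lines
        assert len(a.kept_lines) == 2 and 0 in a.kept_lines

    def test_conjugate_symmetry_of_selection(self):
        mask = iop.make_cartesian_mask(64, 4, "uniform_random", seed=2)
        for k in mask.kept_lines:
            if k not in (0, -32):
                assert -k in mask.kept_lines

    def test_center_band_scheme_keeps_low_frequencies(self):
        mask = iop.make_cartesian_mask(64, 4, "center_band_random", seed=0)
        assert {0, 1, -1, 2, -2} <= set(mask.kept_lines)

    def test_out_of_range_acceleration(self):
        with pytest.raises(ValueError):
            iop.make_cartesian_mask(32, 0.5)
        with pytest.raises(ValueError):
            iop.make_cartesian_mask(32, 64)

    def test_dc_line_required(self):
        with pytest.raises(ValueError):
            iop.SamplingMask(grid_size=8, kept_lines=(1, -1))

    def test_png_export(self, tmp_path):
        mask = iop.make_cartesian_mask(16, 2, "uniform_random", seed=1)
        p = tmp_path / "mask.png"
        mask.save_png(p)
        assert p.exists()


class TestForwardMeasure:
    def test_impulse_spectrum_is_flat(self):
        n = 4
        f = np.zeros((n, n))
        f[0, 0] = 1.0
        model = iop.ForwardModel(iop.make_cartesian_mask(n, 1, "full"))
        g = iop.forward_measure(f, model, 0)
        # oracle: brute-force double-sum DFT of an impulse is identically 1
        oracle = brute_force_dft2(f)
        unshifted = np.fft.ifftshift(g.values)
        assert np.allclose(unshifted, oracle, atol=1e-12)
        assert np.allclose(unshifted, 1.0 + 0j, atol=1e-12)

    def test_matches_brute_force_dft_on_random_image(self, rng):
        n = 8
        f = rng.normal(size=(n, n))
        model = iop.ForwardModel(iop.make_cartesian_mask(n, 1, "full"))
        g = iop.forward_measure(f, model, 0)
        assert np.allclose(np.fft.ifftshift(g.values), brute_force_dft2(f), atol=1e-9)

    def test_noise_per_component_std(self):
        n = 64
        model = iop.ForwardModel(iop.make_cartesian_mask(n, 1, "full"),
                                 iop.NoiseModel(2.5))
        draws = []
        for s in range(30):
            g = iop.forward_measure(np.zeros((n, n)), model, s)
            draws.append(g.values.ravel())
        z = np.concatenate(draws)
        assert abs(z.real.std() / 2.5 - 1) < 0.02
        assert abs(z.imag.std() / 2.5 - 1) < 0.02

    def test_deterministic_given_seed(self, rng):
        n = 16
        model = iop.ForwardModel(iop.make_cartesian_mask(n, 1, "full"),
                                 iop.NoiseModel(1.0))
        f = rng.normal(size=(n, n))
        assert np.array_equal(iop.forward_measure(f, model, 3).values,
                              iop.forward_measure(f, model, 3).values)

    def test_unsampled_lines_exactly_zero(self, rng):
        n = 16
        mask = iop.make_cartesian_mask(n, 4, "uniform_random", seed=0)
        model = iop.ForwardModel(mask, iop.NoiseModel(1.0))
        g = iop.forward_measure(rng.normal(size=(n, n)), model, 0)
        assert np.all(g.values[~mask.as_bool_grid()] == 0)

    def test_shape_mismatch(self, rng):
        model = iop.ForwardModel(iop.make_cartesian_mask(16, 1, "full"))
        with pytest.raises(ValueError):
            iop.forward_measure(rng.normal(size=(8, 8)), model, 0)


class TestReconstruction:
    def test_all_ones_kspace_reconstructs_impulse(self):
        mask = iop.make_cartesian_mask(2, 1, "full")
        g = iop.KSpaceData(values=np.ones((2, 2), dtype=complex), mask=mask)
        rec = iop.pseudoinverse_reconstruct(g)
        assert np.allclose(rec, [[1.0, 0.0], [0.0, 0.0]], atol=1e-12)

    def test_zero_kspace_zero_image(self):
        mask = iop.make_cartesian_mask(8, 1, "full")
        g = iop.KSpaceData(values=np.zeros((8, 8), dtype=complex), mask=mask)
        assert np.all(iop.pseudoinverse_reconstruct(g) == 0)
        assert np.all(iop.magnitude_reconstruct(g) == 0)

    def test_full_mask_zero_noise_round_trip(self, rng):
        n = 32
        model = iop.ForwardModel(iop.make_cartesian_mask(n, 1, "full"))
        f = rng.normal(size=(n, n))
        rec = iop.pseudoinverse_reconstruct(iop.forward_measure(f, model, 0))
        assert np.allclose(rec, f, atol=1e-12)

    def test_magnitude_recovers_nonnegative_object(self, rng):
        n = 16
        model = iop.ForwardModel(iop.make_cartesian_mask(n, 1, "full"))
        f = np.abs(rng.normal(size=(n, n))) + 0.1
        rec = iop.magnitude_reconstruct(iop.forward_measure(f, model, 0))
        assert np.allclose(rec, f, atol=1e-12)

    def test_pure_noise_pixel_std_sigma_over_n(self):
        n, sigma = 256, 4.0
        model = iop.ForwardModel(iop.make_cartesian_mask(n, 1, "full"),
                                 iop.NoiseModel(sigma))
        recs = [iop.pseudoinverse_reconstruct(
            iop.forward_measure(np.zeros((n, n)), model, s)) for s in range(8)]
        std = np.concatenate([r.ravel() for r in recs]).std()
        assert abs(std / (sigma / n) - 1) < 0.02

    def test_pure_noise_magnitude_is_rayleigh(self):
        n, sigma = 256, 4.0
        model = iop.ForwardModel(iop.make_cartesian_mask(n, 1, "full"),
                                 iop.NoiseModel(sigma))
        mags = [iop.magnitude_reconstruct(
            iop.forward_measure(np.zeros((n, n)), model, 100 + s)) for s in range(2)]
        sample = np.concatenate([m.ravel() for m in mags])[:100_000]
        res = stats.kstest(sample, "rayleigh", args=(0, sigma / n))
        assert res.pvalue > 0.01


class TestCorrectedFakeReconstruction:
    def test_zero_noise_is_identity_even_for_negative_pixels(self, rng):
        n = 16
        f = rng.normal(size=(n, n))
        f[3, 4] = -0.5
        model = iop.ForwardModel(iop.make_cartesian_mask(n, 1, "full"))
        out = iop.corrected_fake_reconstruct(f, model, 0)
        assert np.allclose(out, f, atol=1e-12)
        assert abs(out[3, 4] - (-0.5)) < 1e-12

    def test_nonnegative_object_equals_noisy_magnitude_reconstruction(self, rng):
        n = 16
        f = np.abs(rng.normal(size=(n, n)))
        model = iop.ForwardModel(iop.make_cartesian_mask(n, 1, "full"),
                                 iop.NoiseModel(0.8))
        out = iop.corrected_fake_reconstruct(f, model, 7)
        ref = iop.magnitude_reconstruct(iop.forward_measure(f, model, 7))
        assert np.array_equal(out, ref)  # bitwise: same noise draw, same path

    def test_negative_pixels_receive_abs_idft_noise(self, rng):
        n = 16
        f = -np.abs(rng.normal(size=(n, n)))  # entirely negative object
        model = iop.ForwardModel(iop.make_cartesian_mask(n, 1, "full"),
                                 iop.NoiseModel(0.8))
        out = iop.corrected_fake_reconstruct(f, model, 5)
        noise = iop.draw_kspace_noise(model.mask, 0.8, 5)
        expected = f + np.abs(np.fft.ifft2(np.fft.ifftshift(noise)))
        assert np.allclose(out, expected, atol=1e-12)

    def test_undersampled_mask_refused(self, rng):
        n = 16
        mask = iop.make_cartesian_mask(n, 2, "uniform_random", seed=0)
        model = iop.ForwardModel(mask, iop.NoiseModel(1.0))
        with pytest.raises(iop.UnsupportedConfigurationError):
            iop.corrected_fake_reconstruct(rng.normal(size=(n, n)), model, 0)


class TestMeasurementComponent:
    @pytest.mark.parametrize("R", [1, 1.25, 2, 4])
    def test_projector_algebra(self, R, rng):
        n = 32
        mask = (iop.make_cartesian_mask(n, R, "uniform_random", seed=3)
                if R > 1 else iop.make_cartesian_mask(n, 1, "full"))
        f = rng.normal(size=(n, n))
        m1 = iop.measurement_component(f, mask)
        m2 = iop.measurement_component(m1, mask)
        assert np.abs(m2 - m1).max() < 1e-10

    def test_full_mask_returns_object(self, rng):
        n = 16
        f = rng.normal(size=(n, n))
        assert np.allclose(
            iop.measurement_component(f, iop.make_cartesian_mask(n, 1, "full")),
            f, atol=1e-12)

    def test_spectrum_agreement_on_kept_lines(self, rng):
        n = 32
        mask = iop.make_cartesian_mask(n, 4, "uniform_random", seed=1)
        f = rng.normal(size=(n, n))
        fm = iop.measurement_component(f, mask)
        spec_f = np.fft.fftshift(np.fft.fft2(f))
        spec_m = np.fft.fftshift(np.fft.fft2(fm))
        grid = mask.as_bool_grid()
        assert np.abs(spec_f[grid] - spec_m[grid]).max() < 1e-9
        assert np.abs(spec_m[~grid]).max() < 1e-9

    def test_linearity_of_noiseless_forward(self, rng):
        n = 16
        model = iop.ForwardModel(iop.make_cartesian_mask(n, 2, "uniform_random", seed=2))
        f1, f2 = rng.normal(size=(2, n, n))
        g1 = iop.forward_measure(f1, model, 0).values
        g2 = iop.forward_measure(f2, model, 0).values
        g12 = iop.forward_measure(2.0 * f1 + f2, model, 0).values
        assert np.allclose(g12, 2.0 * g1 + g2, atol=1e-9)


class TestKSpacePersistence:
    def test_hdf5_roundtrip(self, rng):
        n = 16
        mask = iop.make_cartesian_mask(n, 2, "uniform_random", seed=4)
        model = iop.ForwardModel(mask, iop.NoiseModel(1.5))
        g = iop.forward_measure(rng.normal(size=(n, n)), model, 8)
        import tempfile, pathlib

        with tempfile.TemporaryDirectory() as d:
            p = pathlib.Path(d) / "kspace.h5"
            g.save_hdf5(p)
            back = iop.KSpaceData.load_hdf5(p)
        assert back.mask.kept_lines == mask.kept_lines
        assert back.noise.kspace_std == 1.5
        assert np.allclose(back.values, g.values, atol=1e-4)  # complex64 store
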