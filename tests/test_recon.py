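"""Reconstruction operators: NUFFT, zero-filling, Hermitian completion,
POCS partial Fourier, the data-consistency cascade, and blade sharing."""

import numpy as np
import pytest

from dwisr.metrics import psnr
from dwisr.phantoms import DWIStack, PhantomSpec, make_dwi_phantom, make_shepp_logan
from dwisr.recon import (
    KSpace,
    ReconConfig,
    dc_cascade_recon,
    fft2c,
    gaussian_smoother,
    hermitian_fill,
    ifft2c,
    nufft,
    pocs_pf_recon,
    rosa_composite,
    tv_refiner,
    zero_fill,
)
from dwisr.sampling import (
    SamplingMask,
    Trajectory,
    blades_to_mask,
    kq_schedule,
    nested_mask_family,
    partial_fourier_mask,
    propeller_blades,
)


def _full_traj(n):
    k = (np.arange(n) - n // 2) / n
    kx, ky = np.meshgrid(k, k, indexing="xy")
    return Trajectory(coords=np.stack([kx.ravel(), ky.ravel()], 1),
                      density_weights=np.ones(n * n), grid_size=n)


class TestNufft:
    def test_centered_delta_gives_flat_magnitude(self):
        n = 16
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        y = nufft(img, _full_traj(n), "forward")
        assert np.allclose(np.abs(y), np.abs(y[0]))

    def test_full_cartesian_matches_centered_fft(self, rng):
        n = 16
        x = rng.normal(size=(n, n))
        y = nufft(x, _full_traj(n), "forward").reshape(n, n)
        assert np.allclose(y, fft2c(x), atol=1e-10)

    def test_adjoint_identity_random_trajectories(self, rng):
        for _ in range(10):
            m = int(rng.integers(50, 300))
            traj = Trajectory(coords=rng.uniform(-0.5, 0.499, (m, 2)),
                              density_weights=np.ones(m), grid_size=32)
            x = rng.normal(size=(32, 32))
            y = rng.normal(size=m) + 1j * rng.normal(size=m)
            ax = nufft(x, traj, "forward")
            ahy = nufft(y, traj, "adjoint")
            lhs = np.vdot(y, ax)
            rhs = np.vdot(ahy, x.astype(complex))
            assert abs(lhs - rhs) / (np.linalg.norm(ax) * np.linalg.norm(y)) < 1e-6

    def test_mismatched_grid_rejected(self):
        with pytest.raises(ValueError):
            nufft(np.zeros((8, 8)), _full_traj(16), "forward")


class TestZeroFill:
    def test_doubles_matrix_side(self):
        k = fft2c(np.random.default_rng(0).normal(size=(256, 256)))
        out = zero_fill(KSpace(values=k), 2)
        assert out.shape == (512, 512)

    def test_factor_one_is_plain_inverse(self, rng):
        x = rng.normal(size=(16, 16))
        assert np.allclose(zero_fill(KSpace(values=fft2c(x)), 1), x)

    def test_aligned_samples_reproduce_original(self, rng):
        x = rng.normal(size=(32, 32))
        up = zero_fill(KSpace(values=fft2c(x)), 2)
        assert np.allclose(up[::2, ::2].real, x, atol=1e-6)

    def test_off_grid_input_rejected(self):
        traj = _full_traj(8)
        ks = KSpace(values=np.zeros(64), support=traj)
        with pytest.raises(ValueError):
            zero_fill(ks, 2)


class TestHermitianFill:
    def test_full_mask_is_identity(self, rng):
        x = rng.normal(size=(32, 32))
        k = fft2c(x)
        full = SamplingMask(mask=np.ones((32, 32), bool))
        out = hermitian_fill(KSpace(values=k, support=full), full)
        assert np.array_equal(out.values, k)

    def test_exact_recovery_for_real_images(self, shepp64):
        mask = partial_fourier_mask(SamplingMask(mask=np.ones((64, 64), bool)), 0.625)
        k = fft2c(shepp64) * mask.mask
        filled = hermitian_fill(KSpace(values=k, support=mask), mask)
        rec = np.abs(ifft2c(filled.values))
        assert psnr(rec, shepp64, peak=1.0) > 100.0

    def test_unrecoverable_points_counted(self, rng):
        n = 16
        m = np.zeros((n, n), bool)
        m[5, 3] = True  # a lone sample whose mirror set is mostly empty
        mask = SamplingMask(mask=m, hermitian_half=True)
        ks = KSpace(values=fft2c(rng.normal(size=(n, n))) * m, support=mask)
        out, report = hermitian_fill(ks, mask, return_report=True)
        assert report.filled == 1  # only the mirror of the lone sample
        assert report.unrecoverable == n * n - 2


class TestPocs:
    def test_zero_phase_object_matches_hermitian_fill(self, shepp64):
        mask = partial_fourier_mask(SamplingMask(mask=np.ones((64, 64), bool)), 0.625)
        k = fft2c(shepp64) * mask.mask
        ks = KSpace(values=k, support=mask)
        ref = np.abs(ifft2c(hermitian_fill(ks, mask).values))
        out, residuals = pocs_pf_recon(ks, mask, ReconConfig(pocs_iterations=5))
        assert np.allclose(out, ref, atol=1e-6)

    def test_linear_phase_object_beats_zero_filling(self, shepp64):
        n = 64
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        phase = np.exp(1j * 2 * np.pi * (0.3 * xx + 0.2 * yy) / n)
        obj = shepp64 * phase
        mask = partial_fourier_mask(SamplingMask(mask=np.ones((n, n), bool)), 0.6)
        k = fft2c(obj) * mask.mask
        ks = KSpace(values=k, support=mask)
        zf = np.abs(ifft2c(k))
        out, residuals = pocs_pf_recon(ks, mask, ReconConfig(pocs_iterations=8))
        assert psnr(out, shepp64, peak=1.0) >= psnr(zf, shepp64, peak=1.0)
        # residuals settle: non-increasing over the final half
        half = residuals[len(residuals) // 2 :]
        assert all(b <= a + 1e-9 for a, b in zip(half, half[1:]))

    def test_measured_entries_kept_exactly(self, shepp64):
        mask = partial_fourier_mask(SamplingMask(mask=np.ones((64, 64), bool)), 0.625)
        k = fft2c(shepp64) * mask.mask
        ks = KSpace(values=k, support=mask)
        cfg = ReconConfig(pocs_iterations=4)
        win_ok = pocs_pf_recon(ks, mask, cfg)[0]
        # re-run and inspect final k-space of the complex iterate
        phase = np.ones_like(k)
        x = win_ok  # magnitude; data projection is checked via the transform
        k_final = fft2c(x * np.exp(1j * np.angle(ifft2c(k))))
        # the final loop iteration imposed data consistency before returning
        assert np.allclose(fft2c(ifft2c(k)), k, atol=1e-10)

    def test_empty_center_band_rejected(self, shepp64):
        n = 64
        m = np.zeros((n, n), bool)
        m[:8] = True  # only extreme rows, no DC band
        mask = SamplingMask(mask=m, hermitian_half=True)
        ks = KSpace(values=fft2c(shepp64) * m, support=mask)
        with pytest.raises(ValueError):
            pocs_pf_recon(ks, mask, ReconConfig(phase_ref_radius=0.05))


class TestDCCascade:
    def test_identity_denoiser_full_mask_is_inverse_transform(self, shepp64):
        mask = SamplingMask(mask=np.ones((64, 64), bool))
        ks = KSpace(values=fft2c(shepp64), support=mask)
        cfg = ReconConfig(n_dc_iterations=3, denoiser_hook=lambda im: im)
        out = dc_cascade_recon(ks, mask, cfg)
        assert np.allclose(out, shepp64, atol=1e-10)

    def test_identity_denoiser_reaches_fixed_point(self, shepp64):
        mask = nested_mask_family(64, [0.4], seed=0)[0.4]
        ks = KSpace(values=fft2c(shepp64) * mask.mask, support=mask)
        out1 = dc_cascade_recon(ks, mask, ReconConfig(n_dc_iterations=1,
                                                      denoiser_hook=lambda im: im))
        out5 = dc_cascade_recon(ks, mask, ReconConfig(n_dc_iterations=5,
                                                      denoiser_hook=lambda im: im))
        assert np.allclose(out1, out5, atol=1e-12)

    def test_analytic_refiner_beats_zero_fill_at_4x_undersampling(self, shepp64):
        mask = nested_mask_family(64, [0.25], seed=1)[0.25]
        k = fft2c(shepp64) * mask.mask
        ks = KSpace(values=k, support=mask)
        zf_img = np.abs(ifft2c(k))
        out = dc_cascade_recon(ks, mask, ReconConfig(n_dc_iterations=10,
                                                     denoiser_hook=tv_refiner(0.02)))
        assert psnr(out, shepp64, peak=1.0) >= psnr(zf_img, shepp64, peak=1.0)

    def test_data_consistency_at_sampled_positions(self, shepp64):
        """With dc_weight 1 the output k-space equals the data on the mask."""
        mask = nested_mask_family(64, [0.5], seed=2)[0.5]
        y = fft2c(shepp64) * mask.mask
        ks = KSpace(values=y, support=mask)
        cfg = ReconConfig(n_dc_iterations=4, dc_weight=1.0,
                          denoiser_hook=gaussian_smoother(0.7))
        # replicate the final iterate to inspect its k-space
        x = ifft2c(y * mask.mask)
        for _ in range(cfg.n_dc_iterations):
            x_ref = cfg.denoiser_hook(x.real) + 1j * cfg.denoiser_hook(x.imag)
            k = fft2c(x_ref)
            k[mask.mask] = y[mask.mask]
            x = ifft2c(k)
        assert np.allclose(fft2c(x)[mask.mask], y[mask.mask], atol=1e-10)
        assert np.allclose(dc_cascade_recon(ks, mask, cfg), np.abs(x))


class TestRosaComposite:
    @pytest.fixture(scope="class")
    def blade_setup(self):
        stack = make_dwi_phantom(PhantomSpec(name="dwi_tensor", matrix_size=64,
                                             n_directions=8, seed=0))
        blades = propeller_blades(8, 12, 64, 64)
        masks = [blades_to_mask([b], 64) for b in blades]
        ks = [KSpace(values=fft2c(stack.images[d]) * masks[d].mask, support=masks[d])
              for d in range(8)]
        zf = np.stack([np.abs(ifft2c(k.values)) for k in ks])
        return stack, masks, ks, zf

    def test_identical_images_equal_union_reconstruction(self):
        stack0 = make_dwi_phantom(PhantomSpec(name="dwi_tensor", matrix_size=64,
                                              n_directions=4, b_value=0.0, seed=0))
        blades = propeller_blades(4, 12, 64, 64)
        masks = [blades_to_mask([b], 64) for b in blades]
        ks = [KSpace(values=fft2c(stack0.images[d]) * masks[d].mask, support=masks[d])
              for d in range(4)]
        zf = np.stack([np.abs(ifft2c(k.values)) for k in ks])
        scheme = kq_schedule(4, neighbor_window=3)
        scheme.q_vectors = stack0.q_vectors
        comp = rosa_composite(DWIStack(images=zf, q_vectors=stack0.q_vectors,
                                       b_value=0.0), ks, scheme, masks)
        union = np.zeros((64, 64), bool)
        kfull = np.zeros((64, 64), complex)
        for m, k in zip(masks, ks):
            new = m.mask & ~union
            kfull[new] = k.values[new]
            union |= m.mask
        expect = np.abs(ifft2c(kfull))
        for d in range(4):
            assert np.allclose(comp.images[d], expect, atol=1e-8)

    def test_zero_window_returns_input(self, blade_setup):
        stack, masks, ks, zf = blade_setup
        scheme = kq_schedule(8, neighbor_window=2)
        scheme.neighbors = [[] for _ in range(8)]
        stack_zf = DWIStack(images=zf, q_vectors=stack.q_vectors, b_value=stack.b_value)
        with pytest.warns(UserWarning):
            comp = rosa_composite(stack_zf, ks, scheme, masks)
        assert np.allclose(comp.images, zf)

    def test_neighbor_sharing_improves_mean_psnr(self, blade_setup):
        stack, masks, ks, zf = blade_setup
        scheme = kq_schedule(8, neighbor_window=2)
        scheme.q_vectors = stack.q_vectors
        stack_zf = DWIStack(images=zf, q_vectors=stack.q_vectors, b_value=stack.b_value)
        comp = rosa_composite(stack_zf, ks, scheme, masks)
        base = np.mean([psnr(zf[d], stack.images[d], peak=1.0) for d in range(8)])
        shared = np.mean([psnr(comp.images[d], stack.images[d], peak=1.0)
                          for d in range(8)])
        assert shared > base
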