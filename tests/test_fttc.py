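"""Fourier-space forward model, Tikhonov inversion, and GCV selection."""

import warnings

import numpy as np
import pytest

from tfm25 import (DEFAULT_MATERIAL, FTTCOptions, NoiseSpec, TractionField,
                   add_noise, centered_surface_grid, centered_volume_grid,
                   displacement_from_pattern, forward_fourier, gcv_score,
                   greens_real, l2_distance, patch_traction, preset_pattern,
                   reconstruct_fttc, select_lambda, tikhonov_invert)
from tfm25.fields import DisplacementField


def band_limited_traction(grid, rng, cutoff=0.5):
    """Real zero-mean traction supported on low modes only (no Nyquist
    content, no zero mode), so the cyclic forward model is exact."""
    th = np.zeros((grid.ny, grid.nx, 3), dtype=complex)
    ny, nx = grid.ny, grid.nx
    mmax, nmax = int(ny * cutoff / 4), int(nx * cutoff / 4)
    for m in range(-mmax, mmax + 1):
        for n in range(-nmax, nmax + 1):
            if m == 0 and n == 0:
                continue
            c = rng.normal(size=3) + 1j * rng.normal(size=3)
            th[m % ny, n % nx] += c
            th[(-m) % ny, (-n) % nx] += c.conj()
    t = np.fft.ifft2(th, axes=(0, 1)).real
    return TractionField(grid, t * (1000.0 / np.abs(t).max()))


@pytest.fixture(scope="module")
def noisy_plane():
    """Noisy surface displacement of the adhesion-array preset."""
    grid = centered_volume_grid(48, 48, 3, 0.5)
    pat = preset_pattern("adhesion_array", ring_radius=6.0, patch_radius=1.5)
    u = displacement_from_pattern(pat, grid, DEFAULT_MATERIAL)
    return add_noise(u.surface_layer(), NoiseSpec(0.2, 5))


class TestForwardFourier:
    def test_zero_traction_zero_displacement(self):
        grid = centered_surface_grid(16, 16, 0.5)
        t = TractionField(grid, np.zeros((16, 16, 3)))
        u = forward_fourier(t, 0.0, DEFAULT_MATERIAL)
        np.testing.assert_array_equal(u.u, 0.0)

    def test_single_mode_stays_single_mode(self):
        """The model is diagonal in k: one traction mode excites exactly
        that displacement mode, scaled by the kernel."""
        grid = centered_surface_grid(16, 16, 0.5)
        th = np.zeros((16, 16, 3), dtype=complex)
        th[2, 3] = [1.0, 2.0, -1.0]
        th[-2, -3] = np.conj(th[2, 3])
        t = TractionField(grid, np.fft.ifft2(th, axes=(0, 1)).real)
        u = forward_fourier(t, 0.7, DEFAULT_MATERIAL)
        uh = np.fft.fft2(u.u, axes=(0, 1))
        mask = np.zeros((16, 16), dtype=bool)
        mask[2, 3] = mask[-2, -3] = True
        assert np.abs(uh[~mask]).max() < 1e-10 * np.abs(uh[mask]).max()

    def test_matches_real_space_convolution(self, rng):
        """Padded cyclic product vs direct summation of the real-space
        kernel (singular centre cell integrated analytically in polar
        form), within 1% away from the window boundary."""
        from numpy.polynomial.legendre import leggauss

        grid = centered_surface_grid(24, 24, 0.5)
        t = band_limited_traction(grid, rng, cutoff=0.3)
        u = forward_fourier(t, 0.0, DEFAULT_MATERIAL, pad_factor=8)
        X, Y = grid.xy_mesh()
        d = grid.dx
        # oracle: u(x_i) = sum_j <G>_cell(x_i - x_j) t_j dA.  The kernel is
        # averaged over each source cell: in polar form for the singular
        # i = j cell, by Gauss quadrature for the near cells, and by its
        # midpoint value far away where it is smooth.
        nphi = 720
        phis = (np.arange(nphi) + 0.5) * 2 * np.pi / nphi
        rmax = np.minimum(d / 2 / np.maximum(np.abs(np.cos(phis)), 1e-12),
                          d / 2 / np.maximum(np.abs(np.sin(phis)), 1e-12))
        Gc = greens_real(np.cos(phis) * 1.0, np.sin(phis) * 1.0, 0.0,
                         DEFAULT_MATERIAL)  # C(phi) = G(e_phi) (degree -1)
        cell0 = np.einsum("g,gij->ij", rmax * (2 * np.pi / nphi), Gc) / d**2
        xg, wg = leggauss(8)
        GX, GY = np.meshgrid(xg * d / 2, xg * d / 2)
        GW = np.outer(wg, wg).ravel() / 4.0  # cell-average weights
        for iy, ix in [(12, 12), (8, 15), (15, 6)]:
            dx = X[iy, ix] - X
            dy = Y[iy, ix] - Y
            r0 = (dx == 0) & (dy == 0)
            G = greens_real(np.where(r0, 1.0, dx), dy + 0.0, 0.0,
                            DEFAULT_MATERIAL)
            G[r0] = 0.0
            near = (np.abs(dx) <= 3 * d + 1e-9) & (np.abs(dy) <= 3 * d + 1e-9) \
                & ~r0
            for jy, jx in np.argwhere(near):
                G[jy, jx] = np.einsum(
                    "g,gij->ij", GW,
                    greens_real(dx[jy, jx] + GX.ravel(),
                                dy[jy, jx] + GY.ravel(), 0.0,
                                DEFAULT_MATERIAL))
            G[r0] = cell0
            val = np.einsum("yxij,yxj->i", G, t.t) * d * d
            err = np.linalg.norm(u.u[iy, ix] - val) / np.linalg.norm(val)
            assert err < 0.01


class TestTikhonov:
    def test_exact_roundtrip_at_zero_lambda(self, rng):
        grid = centered_surface_grid(24, 24, 0.5)
        t0 = band_limited_traction(grid, rng)
        u = forward_fourier(t0, 0.0, DEFAULT_MATERIAL)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = tikhonov_invert(u, 0.0, FTTCOptions(), DEFAULT_MATERIAL)
        np.testing.assert_allclose(rec.t, t0.t, rtol=1e-9,
                                   atol=1e-10 * np.abs(t0.t).max())

    def test_large_lambda_suppresses_everything(self, noisy_plane):
        rec = tikhonov_invert(noisy_plane, 1e6, FTTCOptions(),
                              DEFAULT_MATERIAL)
        assert np.abs(rec.t).max() < 1e-6

    def test_matches_svd_pseudoinverse(self, noisy_plane):
        """Independent oracle: per-mode SVD-filtered pseudoinverse."""
        from tfm25.fttc import _kernel
        opts = FTTCOptions()
        lam = 3e-5
        rec = tikhonov_invert(noisy_plane, lam, opts, DEFAULT_MATERIAL)
        mask, G = _kernel(noisy_plane.grid, 0.0, DEFAULT_MATERIAL, "2.5d")
        uh = np.fft.fft2(noisy_plane.u, axes=(0, 1))
        th = np.zeros_like(uh, dtype=complex)
        sol = np.empty((mask.sum(), 3), dtype=complex)
        for i in range(mask.sum()):
            U, s, Vh = np.linalg.svd(G[i])
            filt = s / (s**2 + lam**2)
            sol[i] = Vh.conj().T @ (filt * (U.conj().T @ uh[mask][i]))
        th[mask] = sol
        ref = np.fft.ifft2(th, axes=(0, 1)).real
        np.testing.assert_allclose(rec.t, ref, rtol=1e-9,
                                   atol=1e-12 * np.abs(ref).max())

    def test_filter_factor_monotonicity(self, noisy_plane):
        """Solution norm non-increasing, residual non-decreasing in lambda."""
        from tfm25.fttc import _kernel
        mask, G = _kernel(noisy_plane.grid, 0.0, DEFAULT_MATERIAL, "2.5d")
        uh = np.fft.fft2(noisy_plane.u, axes=(0, 1))[mask]
        sols, resids = [], []
        for lam in np.geomspace(1e-7, 1e-2, 8):
            rec = tikhonov_invert(noisy_plane, lam, FTTCOptions(),
                                  DEFAULT_MATERIAL)
            th = np.fft.fft2(rec.t, axes=(0, 1))[mask]
            sols.append(np.linalg.norm(th))
            resids.append(np.linalg.norm(
                np.einsum("mij,mj->mi", G, th) - uh))
        assert np.all(np.diff(sols) <= 1e-8 * sols[0])
        assert np.all(np.diff(resids) >= -1e-8 * resids[-1])

    def test_reconstruction_is_real_and_zero_monopole(self, noisy_plane):
        rec = tikhonov_invert(noisy_plane, 1e-5, FTTCOptions(),
                              DEFAULT_MATERIAL)
        assert np.isrealobj(rec.t)
        # the dropped zero mode pins the reconstructed net force to zero
        assert abs(rec.t.sum(axis=(0, 1))).max() < 1e-6 * np.abs(rec.t).max()

    def test_ill_conditioning_warning_at_zero_lambda(self, noisy_plane):
        """A deep observation plane attenuates high-k modes by e^{-kh},
        so the unregularized operator becomes near-singular."""
        with pytest.warns(UserWarning, match="condition number"):
            tikhonov_invert(noisy_plane, 0.0,
                            FTTCOptions(plane_depth=2.0), DEFAULT_MATERIAL)


class TestGCV:
    def test_svd_and_explicit_routes_agree(self, noisy_plane):
        for lam in (1e-5, 1e-4, 1e-3):
            a = gcv_score(lam, noisy_plane, FTTCOptions(), DEFAULT_MATERIAL,
                          method="svd")
            b = gcv_score(lam, noisy_plane, FTTCOptions(), DEFAULT_MATERIAL,
                          method="explicit")
            assert a == pytest.approx(b, rel=1e-10)

    def test_interior_minimum_on_noisy_data(self, noisy_plane):
        lam, curve = select_lambda(noisy_plane, FTTCOptions(),
                                   DEFAULT_MATERIAL)
        assert lam > 0
        i = int(np.argmin(curve[:, 1]))
        assert 0 < i < len(curve) - 1

    def test_saturates_increasing_at_large_lambda(self, noisy_plane):
        scores = [gcv_score(lam, noisy_plane, FTTCOptions(), DEFAULT_MATERIAL)
                  for lam in (1.0, 10.0, 100.0)]
        assert np.all(np.isfinite(scores))
        assert scores[0] <= scores[1] <= scores[2]

    def test_selection_matches_dense_grid_search(self, noisy_plane):
        opts = FTTCOptions()
        lam, curve = select_lambda(noisy_plane, opts, DEFAULT_MATERIAL)
        dense = np.geomspace(curve[0, 0], curve[-1, 0], 10 * len(curve))
        scores = [gcv_score(l, noisy_plane, opts, DEFAULT_MATERIAL)
                  for l in dense]
        best = dense[int(np.argmin(scores))]
        assert np.log(lam) == pytest.approx(np.log(best), abs=0.15)

    def test_deterministic(self, noisy_plane):
        l1, _ = select_lambda(noisy_plane, FTTCOptions(), DEFAULT_MATERIAL)
        l2, _ = select_lambda(noisy_plane, FTTCOptions(), DEFAULT_MATERIAL)
        assert l1 == l2


class TestReconstructPipeline:
    def test_gcv_beats_unregularized_on_noise(self):
        """At sigma_N/<||u||> = 0.2 the GCV solution's d_L2 improves on the
        lambda = 0 solution for every seed tried."""
        grid = centered_volume_grid(32, 32, 3, 0.5)
        pat = preset_pattern("adhesion_array", ring_radius=4.0,
                             patch_radius=1.2, adhesion_ft_un=0.15)
        u = displacement_from_pattern(pat, grid, DEFAULT_MATERIAL)
        truth = patch_traction(pat, grid.surface())
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            noisy = add_noise(u.surface_layer(), NoiseSpec(0.2, seed))
            res = reconstruct_fttc(noisy, FTTCOptions(), DEFAULT_MATERIAL)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                raw = tikhonov_invert(noisy, 0.0, FTTCOptions(),
                                      DEFAULT_MATERIAL)
            if l2_distance(res.traction, truth) < l2_distance(raw, truth):
                wins += 1
        assert wins >= 0.95 * n_seeds

    def test_2d_mode_ignores_normal_data(self, noisy_plane):
        """With a strong normal component, the tangential result of 2D FTTC
        differs measurably from 2.5D (the coupling is real); 2D output has
        no normal traction at all."""
        grid = centered_volume_grid(32, 32, 3, 0.5)
        pat = preset_pattern("indenter", radius=3.0)
        u = displacement_from_pattern(pat, grid, DEFAULT_MATERIAL)
        us = u.surface_layer()
        r2d = reconstruct_fttc(us, FTTCOptions(mode="2d",
                                               lambda_policy=1e-5),
                               DEFAULT_MATERIAL)
        r25 = reconstruct_fttc(us, FTTCOptions(mode="2.5d",
                                               lambda_policy=1e-5),
                               DEFAULT_MATERIAL)
        assert np.all(r2d.traction.t[..., 2] == 0.0)
        tan_diff = np.abs(r2d.traction.t[..., :2]
                          - r25.traction.t[..., :2]).max()
        assert tan_diff > 0.01 * np.abs(r25.traction.t).max()

    def test_accepts_volume_input_via_surface_layer(self):
        grid = centered_volume_grid(16, 16, 3, 0.5)
        pat = preset_pattern("indenter", radius=2.0)
        u = displacement_from_pattern(pat, grid, DEFAULT_MATERIAL)
        res = reconstruct_fttc(u, FTTCOptions(lambda_policy=1e-5),
                               DEFAULT_MATERIAL)
        assert res.traction.t.shape == (16, 16, 3)
        assert "residual_norm" in res.diagnostics

    def test_volume_rejected_by_low_level_ops(self, rng):
        grid = centered_volume_grid(8, 8, 3, 0.5)
        u = DisplacementField(grid, rng.normal(size=(3, 8, 8, 3)))
        with pytest.raises(ValueError, match="plane"):
            tikhonov_invert(u, 1e-4, FTTCOptions(), DEFAULT_MATERIAL)
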