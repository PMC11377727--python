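import cmath
import math

import numpy as np
import pytest
from scipy import ndimage

import wstomo as w
from wstomo._fft import fft2c, fft3c


def bruteforce_first_order(V_hat, grid, lam, n_m, z_D):
    """Sample-by-sample Fourier-diffraction-theorem oracle (independent)."""
    km = n_m / lam
    dkx, dky, dkz = grid.freq_pitch
    nx, ny, nz = grid.shape
    spec = np.zeros((nx, ny), dtype=complex)
    for i in range(nx):
        for j in range(ny):
            kx = (i - nx // 2) * dkx
            ky = (j - ny // 2) * dky
            kT2 = kx * kx + ky * ky
            if kT2 >= km * km:
                continue
            kz = math.sqrt(km * km - kT2)
            iz = nz // 2 + math.floor((kz - km) / dkz + 0.5)
            if iz < 0 or iz >= nz:
                continue
            pref = 1j / (4 * math.pi * kz) * cmath.exp(2j * math.pi * (kz - km) * z_D)
            spec[i, j] = V_hat[i, j, iz] * pref
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(spec))) / grid.pixel_area


class TestScatteringPotential:
    def test_zero_contrast_gives_zero_potential(self):
        vol = w.bead_phantom((8, 8, 8), (0.5, 0.5, 0.5), [], n_m=1.33)
        assert np.all(w.scattering_potential(vol, 0.5) == 0)

    def test_bead_in_oil_value(self):
        vol = w.bead_phantom(
            (16, 16, 16), (0.5, 0.5, 0.5), [((0, 0, 0), 3.0, 1.594)], n_m=1.58
        )
        V = w.scattering_potential(vol, 0.483)
        expected = (2 * np.pi / 0.483) ** 2 * (1.594**2 - 1.58**2)
        assert np.max(V.real) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(169.2252 * 0.044436, rel=1e-4)

    def test_doubling_wavelength_quarters_potential(self, bead_vol_16):
        V1 = w.scattering_potential(bead_vol_16, 0.5)
        V2 = w.scattering_potential(bead_vol_16, 1.0)
        assert np.allclose(V2, V1 / 4)


class TestFirstOrderField:
    def test_matches_bruteforce_oracle(self, grid16):
        rng = np.random.default_rng(0)
        V_hat = rng.normal(size=(16, 16, 16)) + 1j * rng.normal(size=(16, 16, 16))
        lam, n_m, z_D = 0.6, 1.33, 12.0
        shell = w.build_shell(grid16, lam, n_m, z_D)
        u = w.first_order_field(V_hat, shell)
        oracle = bruteforce_first_order(V_hat, grid16, lam, n_m, z_D)
        assert np.max(np.abs(u.data - oracle)) <= 1e-10 * np.max(np.abs(oracle))

    def test_zero_spectrum_gives_zero_field(self, grid16):
        shell = w.build_shell(grid16, 0.5, 1.33, 10.0)
        u = w.first_order_field(np.zeros((16, 16, 16), complex), shell)
        assert np.all(u.data == 0)

    def test_impulse_at_dc_voxel(self, grid16):
        """A unit impulse at the cap's DC voxel excites only k_T = 0, with the
        envelope prefactor j/(4πk_m)."""
        shell = w.build_shell(grid16, 0.5, 1.33, z_D=7.0)
        V_hat = np.zeros((16, 16, 16), complex)
        V_hat[8, 8, 8] = 1.0
        u = w.first_order_field(V_hat, shell)
        spec = fft2c(u.data, grid16.pixel_area)
        k_m = 1.33 / 0.5
        expected = 1j / (4 * np.pi * k_m)  # exp(2πj(k_z−k_m)z_D) = 1 at DC
        assert spec[8, 8] == pytest.approx(expected, rel=1e-12)
        spec[8, 8] = 0
        assert np.max(np.abs(spec)) < 1e-12 * abs(expected)

    def test_linearity(self, grid16):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(16, 16, 16)) + 1j * rng.normal(size=(16, 16, 16))
        B = rng.normal(size=(16, 16, 16)) + 1j * rng.normal(size=(16, 16, 16))
        shell = w.build_shell(grid16, 0.5, 1.33, 10.0)
        uA = w.first_order_field(A, shell).data
        uB = w.first_order_field(B, shell).data
        uAB = w.first_order_field(2 * A + 3 * B, shell).data
        assert np.allclose(uAB, 2 * uA + 3 * uB, atol=1e-12)

    def test_grid_mismatch_rejected(self, grid16):
        shell = w.build_shell(grid16, 0.5, 1.33, 10.0)
        with pytest.raises(ValueError, match="does not match"):
            w.first_order_field(np.zeros((8, 8, 8), complex), shell)


class TestRytovIntensity:
    def test_no_sample_gives_unit_intensity(self):
        u = w.ComplexField(np.zeros((8, 8), complex), 0.5, 10.0, 0.5)
        assert np.all(w.rytov_intensity(u).data == 1.0)

    def test_pure_phase_is_invisible_at_its_own_plane(self):
        u = w.ComplexField(1j * np.linspace(0, 2, 64).reshape(8, 8), 0.5, 0.0, 0.5)
        assert np.allclose(w.rytov_intensity(u).data, 1.0)

    def test_real_exponent_closed_form(self):
        u = w.ComplexField(np.full((4, 4), 0.1 + 0j), 0.5, 0.0, 0.5)
        assert np.allclose(w.rytov_intensity(u).data, np.exp(0.2))


class TestBinPixels:
    def test_constant_image(self):
        f = w.IntensityFrame(np.ones((4, 4)), 0.5, 10.0, 0.4)
        out = w.bin_pixels(f, 2)
        assert out.data.shape == (2, 2)
        assert np.all(out.data == 1.0)
        assert out.pitch == pytest.approx(0.8)

    def test_block_mean(self):
        f = w.IntensityFrame(np.array([[0.0, 2.0], [4.0, 6.0]]), 0.5, 10.0, 0.4)
        assert w.bin_pixels(f, 2).data == pytest.approx(np.array([[3.0]]))

    def test_identity_at_s1(self):
        data = np.random.default_rng(0).uniform(size=(6, 6))
        f = w.IntensityFrame(data, 0.5, 10.0, 0.4)
        assert np.array_equal(w.bin_pixels(f, 1).data, data)

    def test_mean_preserved(self):
        data = np.random.default_rng(1).uniform(size=(8, 8))
        f = w.IntensityFrame(data, 0.5, 10.0, 0.4)
        assert w.bin_pixels(f, 4).data.mean() == pytest.approx(data.mean(), rel=1e-12)

    def test_bin_replicate_bin_idempotent(self):
        from wstomo.forward import replicate_pixels

        data = np.random.default_rng(2).uniform(size=(8, 8))
        f = w.IntensityFrame(data, 0.5, 10.0, 0.4)
        once = w.bin_pixels(f, 2)
        again = w.bin_pixels(
            w.IntensityFrame(replicate_pixels(once.data, 2), 0.5, 10.0, 0.4), 2
        )
        assert np.allclose(again.data, once.data, atol=1e-14)

    def test_non_divisible_shape_rejected(self):
        f = w.IntensityFrame(np.ones((5, 4)), 0.5, 10.0, 0.4)
        with pytest.raises(ValueError, match="divisible"):
            w.bin_pixels(f, 2)


class TestSimulateScan:
    def _cfg(self, **over):
        base = dict(
            wavelengths=tuple(w.scan_schedule(0.43, 1.2, 5)), n_m=1.33,
            z_D=10.0, sensor_pitch=0.8, upsample=2, nz=16, dz=0.4,
            guard=0, passes=1,
        )
        base.update(over)
        return w.ScanConfig(**base)

    def test_zero_contrast_volume_gives_unit_frames(self):
        vol = w.bead_phantom((32, 32, 16), (0.4, 0.4, 0.4), [], n_m=1.33)
        frames, _ = w.simulate_scan(vol, self._cfg())
        for f in frames:
            assert np.allclose(f.data, 1.0, atol=1e-12)

    def test_noise_is_deterministic_given_seed(self):
        vol = w.bead_phantom(
            (32, 32, 16), (0.4, 0.4, 0.4), [((0, 0, 0), 2.0, 1.36)], n_m=1.33
        )
        cfg = self._cfg(photons=1000.0, read_noise=0.01, seed=11)
        a, _ = w.simulate_scan(vol, cfg)
        b, _ = w.simulate_scan(vol, cfg)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.data, fb.data)

    def test_wavelength_diversity(self):
        vol = w.bead_phantom(
            (32, 32, 16), (0.4, 0.4, 0.4), [((0, 0, 0), 2.0, 1.36)], n_m=1.33
        )
        frames, _ = w.simulate_scan(vol, self._cfg())
        dists = [
            np.linalg.norm(frames[i].data - frames[j].data)
            for i in range(len(frames))
            for j in range(i + 1, len(frames))
        ]
        assert max(dists) > 0

    def test_guard_band_crops_frames(self):
        vol = w.bead_phantom((40, 40, 16), (0.4, 0.4, 0.4), [], n_m=1.33)
        frames, _ = w.simulate_scan(vol, self._cfg(guard=4))
        assert frames[0].data.shape == (16, 16)  # (40-8)/2


class TestWeakObjectConsistency:
    def test_rytov_matches_angular_spectrum_on_thin_slab(self):
        """Independent cross-check: the Fourier-diffraction forward model vs
        angular-spectrum propagation of exp(jφ) for a thin weak phase slab."""
        shape, pitch = (64, 64, 16), (0.5, 0.5, 0.5)
        rng = np.random.default_rng(0)
        pat = np.zeros(shape[:2])
        pat[20:44, 20:44] = rng.uniform(0.5, 1.0, (24, 24))
        pat = ndimage.gaussian_filter(pat, 2)
        dn, n_m, lam, z_D = 0.002, 1.33, 0.5, 30.0

        n = np.full(shape, n_m)
        n[:, :, shape[2] // 2] += dn * pat
        vol = w.RIVolume(n.astype(complex), pitch, n_m)
        grid = vol.grid
        V_hat = fft3c(w.scattering_potential(vol, lam), grid.voxel_volume)
        shell = w.build_shell(grid, lam, n_m, z_D)
        I_model = w.rytov_intensity(w.first_order_field(V_hat, shell)).data

        # oracle implemented only here: angular-spectrum envelope propagator
        phi = 2 * np.pi / lam * dn * pat * pitch[2]
        U0 = np.exp(1j * phi)
        kx = np.fft.fftfreq(shape[0], pitch[0])
        KX, KY = np.meshgrid(kx, kx, indexing="ij")
        km = n_m / lam
        rad = km * km - KX * KX - KY * KY
        kz = np.sqrt(np.maximum(rad, 0))
        H = np.where(rad > 0, np.exp(2j * np.pi * (kz - km) * z_D), 0)
        I_oracle = np.abs(np.fft.ifft2(np.fft.fft2(U0) * H)) ** 2

        rms = np.sqrt(np.mean((I_model - I_oracle) ** 2) / np.mean(I_oracle**2))
        assert rms < 0.02
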