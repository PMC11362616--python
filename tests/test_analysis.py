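"""Above-noise means, line profiles, FWHM and contrast measurements."""

import numpy as np
import pytest

from pa2p.analysis import (
    NoPeakError,
    ProfileMeasurement,
    contrast_report,
    estimate_fwhm,
    extract_line_profile,
    mean_above_noise,
)


class TestMeanAboveNoise:
    def test_uniform_signal_over_zero_reference(self):
        frame = np.full((32, 32), 10.0)
        ref = np.zeros((32, 32))
        res = mean_above_noise(frame, ref, k_sigma=3.0)
        assert res.has_signal
        assert res.mean == pytest.approx(10.0)
        assert res.n_pixels == frame.size

    def test_disk_on_poisson_background(self):
        """A bright disk on Poisson background: the measured mean is within
        5% of the disk mean and the mask covers >= 95% of the true disk."""
        rng = np.random.default_rng(17)
        ny = nx = 128
        yy, xx = np.mgrid[:ny, :nx]
        disk = (yy - 64) ** 2 + (xx - 64) ** 2 <= 20**2
        frame = rng.poisson(2.0, (ny, nx)).astype(float)
        frame[disk] = rng.poisson(50.0, int(disk.sum()))
        ref = rng.poisson(2.0, (ny, nx)).astype(float)
        res = mean_above_noise(frame, ref, k_sigma=3.0)
        assert res.has_signal
        assert res.mean == pytest.approx(50.0, rel=0.05)
        assert (res.mask & disk).sum() >= 0.95 * disk.sum()

    def test_frame_equal_to_reference_flags_no_signal(self):
        rng = np.random.default_rng(3)
        ref = rng.poisson(5.0, (64, 64)).astype(float)
        res = mean_above_noise(np.zeros_like(ref), ref)
        assert not res.has_signal
        assert np.isnan(res.mean)

    def test_constant_offset_behaviour_documented(self):
        """Adding c to both frame and reference shifts threshold and values
        equally, so the mask and the (mean - c) are unchanged."""
        rng = np.random.default_rng(5)
        ref = rng.poisson(2.0, (64, 64)).astype(float)
        frame = ref + 0.0
        frame[10:20, 10:20] += 40.0
        base = mean_above_noise(frame, ref)
        shifted = mean_above_noise(frame + 7.0, ref + 7.0)
        np.testing.assert_array_equal(base.mask, shifted.mask)
        assert shifted.mean - 7.0 == pytest.approx(base.mean)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_above_noise(np.zeros((4, 4)), np.zeros((5, 5)))


class TestLineProfile:
    def test_constant_image_gives_constant_profile(self):
        img = np.full((32, 32), 7.0)
        p = extract_line_profile(img, ((16, 2), (16, 29)), width=3)
        np.testing.assert_allclose(p.values, 7.0)

    def test_width_one_equals_row_sampling(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 10, (16, 32))
        p = extract_line_profile(img, ((8, 0), (8, 31)), width=1)
        np.testing.assert_allclose(p.values, img[8, :], atol=1e-9)

    def test_peak_position_against_ground_truth_filament(self):
        """Profile across a rendered vertical line: argmax within one pixel
        of the known centre."""
        img = np.zeros((32, 32))
        img[:, 13] = 50.0
        img[:, 14] = 30.0  # sub-pixel centre near 13.4
        p = extract_line_profile(img, ((16, 0), (16, 31)), width=5, pixel_size=40.0)
        assert abs(p.positions[np.argmax(p.values)] / 40.0 - 13.0) <= 1.0

    def test_positions_in_physical_units(self):
        img = np.zeros((8, 8))
        p = extract_line_profile(img, ((4, 0), (4, 7)), pixel_size=40.0)
        assert p.positions[1] - p.positions[0] == pytest.approx(40.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            extract_line_profile(np.zeros((8, 8)), ((4, 4), (4, 4)))

    def test_endpoint_outside_rejected(self):
        with pytest.raises(ValueError):
            extract_line_profile(np.zeros((8, 8)), ((4, 0), (4, 99)))


class TestEstimateFWHM:
    def _gauss_profile(self, sigma=50.0, peak=100.0, bg=5.0, step=10.0, noise_rng=None):
        x = np.arange(0.0, 600.0, step)
        y = bg + peak * np.exp(-((x - 300.0) ** 2) / (2 * sigma**2))
        if noise_rng is not None:
            y = noise_rng.poisson(y).astype(float)
        return ProfileMeasurement(positions=x, values=y)

    def test_noiseless_gaussian_closed_form(self):
        m = estimate_fwhm(self._gauss_profile(sigma=50.0))
        assert m.fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 50.0, rel=1e-6)

    def test_filament_scale_width_under_poisson_noise(self):
        """sigma = 32 nm (FWHM ~75 nm, the scale of antibody-stained
        microtubules) with Poisson noise: fitted FWHM within +-8 nm."""
        rng = np.random.default_rng(23)
        m = estimate_fwhm(
            self._gauss_profile(sigma=32.0, peak=200.0, step=15.0, noise_rng=rng)
        )
        assert m.fwhm == pytest.approx(75.34, abs=8.0)

    def test_scale_equivariance(self):
        base = self._gauss_profile()
        f0 = estimate_fwhm(base).fwhm
        for s in (0.5, 2.0):
            scaled = ProfileMeasurement(positions=base.positions * s, values=base.values)
            assert estimate_fwhm(scaled).fwhm == pytest.approx(s * f0, rel=1e-6)

    def test_raw_interpolation_cross_check(self):
        m_fit = estimate_fwhm(self._gauss_profile(step=2.0))
        m_raw = estimate_fwhm(self._gauss_profile(step=2.0), raw=True)
        assert m_raw.fwhm == pytest.approx(m_fit.fwhm, rel=0.02)

    def test_flat_profile_raises(self):
        flat = ProfileMeasurement(
            positions=np.arange(0.0, 500.0, 10.0),
            values=np.full(50, 5.0),
        )
        with pytest.raises(NoPeakError):
            estimate_fwhm(flat)


class TestContrastReport:
    def _filament_image(self, bg):
        img = np.full((32, 64), float(bg))
        img[:, 30] += 100.0
        img[:, 31] += 60.0
        return img

    def test_identical_images_ratio_one(self):
        img = self._filament_image(bg=5.0)
        rep = contrast_report(img, img, ((16, 0), (16, 63)))
        assert rep["ratio"] == pytest.approx(1.0)

    def test_added_background_lowers_contrast(self):
        a = self._filament_image(bg=5.0)
        b = a + 20.0
        rep = contrast_report(a, b, ((16, 0), (16, 63)))
        assert rep["sbr_b"] < rep["sbr_a"]
        assert rep["ratio"] > 1.0

    def test_zero_background_flagged(self):
        a = self._filament_image(bg=0.0)
        rep = contrast_report(a, a + 1.0, ((16, 0), (16, 63)))
        assert any("zero-background" in f for f in rep["flags"])

    def test_simulated_two_photon_beats_one_photon(self):
        """Out-of-focus activation adds background: images with a larger
        out-of-focus dose fraction must score a lower SBR (ground-truth
        photon bookkeeping from the axial dose profiles)."""
        from pa2p.optics import BeamModel, out_of_focus_fraction, plane_integrated_dose

        z = np.linspace(-5000.0, 5000.0, 2001)
        in_focus_signal = 100.0
        images = {}
        fracs = {}
        for mode, order in (("2pa", 2), ("1pa", 1)):
            beam = BeamModel(process_order=order, rayleigh_range=500.0)
            profile = plane_integrated_dose(beam, z)
            if order == 1:
                frac = 1.0 - 1000.0 / (z[-1] - z[0])  # uniform dose bookkeeping
            else:
                frac = out_of_focus_fraction(profile, 500.0)
            fracs[mode] = frac
            # out-of-focus dose shows up as diffuse background counts
            bg = 50.0 * frac / (1.0 - frac)
            img = np.full((32, 64), bg)
            img[:, 30] += in_focus_signal
            images[mode] = img
        assert fracs["1pa"] > fracs["2pa"]
        rep = contrast_report(images["2pa"], images["1pa"], ((16, 0), (16, 63)))
        assert rep["sbr_a"] > rep["sbr_b"]
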