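"""Optics: asphere sag, focal shells, PSF/magnification/mask models, and the
bead-stack characterization fits."""

import numpy as np
import pytest

from endosim.optics import (
    AsphereProfile,
    ImagingSurface,
    IntensityMask,
    MagnificationModel,
    PSFModel,
    asphere_sag,
    characterize_psf_stack,
    corrected_model,
    effective_fov_radius,
    intensity_mask_value,
    magnification_factor,
    psf_at_radius,
    radial_calibration,
    surface_z,
    uncorrected_model,
)


class TestAsphereSag:
    def test_flat_profile_has_zero_sag(self):
        prof = AsphereProfile(c=0.0)
        r = np.linspace(0, 200, 11)
        assert np.allclose(asphere_sag(prof, r), 0.0)

    def test_reduces_to_spherical_sag(self):
        R = 400.0
        prof = AsphereProfile(c=1.0 / R, k=0.0)
        r = np.linspace(0, 250, 23)
        assert np.allclose(asphere_sag(prof, r), R - np.sqrt(R**2 - r**2))

    def test_matches_symbolic_evaluation(self, rng):
        import sympy as sp

        c, k = 1e-3, -0.8
        alpha = (1e-7, -3e-12, 5e-17)
        rs = sp.symbols("r")
        expr = c * rs**2 / (1 + sp.sqrt(1 - (1 + k) * c**2 * rs**2))
        for n, a in enumerate(alpha, start=1):
            expr += a * rs ** (2 * n)
        prof = AsphereProfile(c=c, k=k, alpha=alpha)
        for r in rng.uniform(0, 300, 8):
            expected = float(expr.subs(rs, r))
            assert asphere_sag(prof, r) == pytest.approx(expected, rel=1e-12)

    def test_even_in_r(self, rng):
        prof = AsphereProfile(c=5e-4, k=-1.2, alpha=(1e-8,))
        r = rng.uniform(0, 300, 20)
        assert np.allclose(asphere_sag(prof, r), asphere_sag(prof, -r))

    def test_domain_violation_raises(self):
        prof = AsphereProfile(c=0.01, k=0.0)
        with pytest.raises(ValueError):
            asphere_sag(prof, 200.0)


class TestSurface:
    def test_apex(self):
        s = ImagingSurface(curvature_radius=400.0, apex_z=12.0)
        assert surface_z(s, 0.0, 0.0) == pytest.approx(12.0)

    def test_sag_at_250um_on_400um_shell(self):
        s = ImagingSurface(curvature_radius=400.0)
        z = surface_z(s, 250.0, 0.0)
        assert z == pytest.approx(400 - np.sqrt(400**2 - 250**2), abs=1e-9)
        assert z == pytest.approx(87.8, abs=0.1)

    def test_flat_limit(self):
        s = ImagingSurface(curvature_radius=np.inf, apex_z=5.0)
        assert np.allclose(surface_z(s, np.array([0, 100, 200]), 0.0), 5.0)

    def test_depends_only_on_radial_distance(self, rng):
        s = ImagingSurface(curvature_radius=300.0)
        r = 120.0
        th = rng.uniform(0, 2 * np.pi, 10)
        z = surface_z(s, r * np.cos(th), r * np.sin(th))
        assert np.allclose(z, z[0])

    def test_outside_support_raises(self):
        s = ImagingSurface(curvature_radius=100.0)
        with pytest.raises(ValueError):
            surface_z(s, 90.0, 90.0)


class TestPSFModel:
    def test_constant_model_uniform_over_fov(self):
        m = PSFModel(lateral=(1.0, 0, 0), axial=(8.0, 0, 0))
        assert psf_at_radius(m, 0.0) == psf_at_radius(m, 200.0) == (1.0, 8.0)

    def test_quartic_evaluation(self):
        m = PSFModel(lateral=(1.0, 1e-5, 0), axial=(8.0, 2e-4, 3e-9))
        lat, ax = psf_at_radius(m, 100.0)
        assert lat == pytest.approx(1.0 + 1e-5 * 100**2)
        assert ax == pytest.approx(8.0 + 2e-4 * 100**2 + 3e-9 * 100**4)

    def test_corrected_default_axial_below_threshold_inside_fov(self):
        model = corrected_model()
        r_eff = effective_fov_radius(model.psf)
        r = np.linspace(0, r_eff - 1e-6, 50)
        assert np.all(model.psf.axial_fwhm(r) < 10.0)

    def test_uncorrected_default_axial_strictly_increasing(self):
        psf = uncorrected_model().psf
        r = np.linspace(0, 250, 100)
        assert np.all(np.diff(psf.axial_fwhm(r)) > 0)

    def test_effective_fov_crossing_matches_polynomial_root(self):
        psf = uncorrected_model().psf
        r_eff = effective_fov_radius(psf, threshold=10.0)
        # independent root: solve c4 r^4 + c2 r^2 + (c0 - 10) = 0 for r^2
        c0, c2, c4 = psf.axial
        r2 = np.roots([c4, c2, c0 - 10.0])
        r_ref = np.sqrt(r2[(r2.imag == 0) & (r2.real > 0)].real.min())
        assert r_eff == pytest.approx(r_ref, abs=0.1)

    def test_outside_support_raises(self):
        with pytest.raises(ValueError):
            psf_at_radius(corrected_model().psf, 400.0)


class TestMagnification:
    def test_printed_center_values(self):
        assert magnification_factor(corrected_model().magnification, 0.0) == 0.76
        assert magnification_factor(uncorrected_model().magnification, 0.0) == 0.73

    def test_printed_quadratic_at_200um(self):
        m = corrected_model().magnification
        assert magnification_factor(m, 200.0) == pytest.approx(1.4152)

    def test_radial_calibration_identity_for_uniform_magnification(self):
        m = MagnificationModel(0.8, 0.0, 0.0)
        rho = np.array([0.0, 50.0, 200.0])
        assert np.allclose(radial_calibration(m, rho), rho, atol=1e-6)

    def test_radial_calibration_compresses_under_growing_magnification(self):
        m = corrected_model().magnification
        r = radial_calibration(m, np.array([250.0]))[0]
        assert 0 < r < 250.0


class TestIntensityMask:
    def test_uniform_mask_is_one_everywhere(self):
        m = IntensityMask()
        assert np.allclose(intensity_mask_value(m, np.linspace(0, 250, 10)), 1.0)

    def test_normalized_at_center(self):
        for m in (IntensityMask(sigma_um=150.0),
                  IntensityMask(table=((0, 100, 200), (2.0, 1.0, 0.5)))):
            assert intensity_mask_value(m, 0.0) == pytest.approx(1.0)

    def test_tabulated_midpoint_is_mean_of_neighbors(self):
        m = IntensityMask(table=((0.0, 100.0), (1.0, 0.4)))
        v = intensity_mask_value(m, 50.0)
        assert v == pytest.approx(0.7)


def _gauss_bead(shape, fwhm_xyz, voxel, centers=None):
    z, y, x = np.indices(shape).astype(float)
    c = [s // 2 for s in shape] if centers is None else centers
    sds = [f / (2 * np.sqrt(2 * np.log(2))) / v for f, v in zip(fwhm_xyz, voxel)]
    return np.exp(-0.5 * (((z - c[0]) / sds[2]) ** 2 + ((y - c[1]) / sds[1]) ** 2
                          + ((x - c[2]) / sds[0]) ** 2))


class TestPSFCharacterization:
    VOX = (0.25, 0.25, 0.25)

    def test_recovers_axial_fwhm_within_one_percent(self):
        stack = _gauss_bead((81, 41, 41), (1.0, 1.0, 3.0), self.VOX)
        res = characterize_psf_stack([stack], np.array([0.0]), voxel_size=self.VOX)
        assert res["table"][0]["fwhm_ax_um"] == pytest.approx(3.0, rel=0.01)

    def test_double_lobed_axial_profile_reports_peak_separation(self):
        a = _gauss_bead((161, 41, 41), (1.0, 1.0, 2.0), self.VOX, centers=(64, 20, 20))
        b = _gauss_bead((161, 41, 41), (1.0, 1.0, 2.0), self.VOX, centers=(96, 20, 20))
        res = characterize_psf_stack([a + b], np.array([150.0]), voxel_size=self.VOX)
        rec = res["table"][0]
        assert rec["double_lobed"]
        assert rec["fwhm_ax_um"] == pytest.approx(32 * 0.25, rel=0.05)

    def test_radially_symmetric_bead_has_equal_lateral_fwhms(self):
        stack = _gauss_bead((41, 41, 41), (1.2, 1.2, 4.0), self.VOX)
        res = characterize_psf_stack([stack], np.array([0.0]), voxel_size=self.VOX)
        rec = res["table"][0]
        assert rec["fwhm_x_um"] == pytest.approx(rec["fwhm_y_um"], rel=1e-3)

    def test_quartic_coefficients_recovered_from_noise_free_curves(self):
        gen = (8.0, 2e-4, 2e-9)  # axial FWHM(r) = c0 + c2 r^2 + c4 r^4
        radii = np.array([0.0, 60.0, 120.0, 180.0, 240.0])
        stacks = []
        for r in radii:
            ax = gen[0] + gen[1] * r**2 + gen[2] * r**4
            stacks.append(_gauss_bead((121, 33, 33), (1.0, 1.0, ax),
                                      (0.25, 0.25, 0.5)))
        res = characterize_psf_stack(stacks, radii, voxel_size=(0.25, 0.25, 0.5))
        fit = res["axial_fit"]
        r = np.linspace(0, 240, 25)
        gen_curve = gen[0] + gen[1] * r**2 + gen[2] * r**4
        fit_curve = fit[0] + fit[1] * r**2 + fit[2] * r**4
        assert np.allclose(fit_curve, gen_curve, rtol=0.02)
        # effective FOV radius: where the generating curve crosses 10 µm
        assert res["effective_fov_radius"] == pytest.approx(
            np.interp(10.0, gen_curve, r), rel=0.05)
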