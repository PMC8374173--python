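"""Crater sizing, particle mapping, impactor picomoles, capture efficiency."""

import math

import numpy as np
import pytest

from impactquant.calibration import CalibrationFit, droplet_picomoles
from impactquant.craters import (
    ParticleCraterCalibration,
    analyze_crater,
    capture_efficiency,
    crater_diameter,
    fit_ellipse,
    impactor_picomoles,
    load_pc_calibration,
    particle_diameter,
    save_pc_calibration,
)
from impactquant.imaging import EllipseShape, Roi, roi_pixel_mask
from impactquant.synth import Deposit, SynthScene, render_scene


class TestFitEllipse:
    def test_circle_from_points(self):
        t = np.linspace(0, 2 * math.pi, 200, endpoint=False)
        pts = np.column_stack([50 + 10 * np.cos(t), 50 + 10 * np.sin(t)])
        major, minor, center, _ = fit_ellipse(points=pts)
        assert major == pytest.approx(20.0, rel=1e-6)
        assert minor == pytest.approx(20.0, rel=1e-6)
        assert center[0] == pytest.approx(50.0, abs=1e-6)

    def test_canonical_axis_aligned_mask(self):
        roi = Roi("e", EllipseShape(cx=64, cy=64, a=30, b=10), "signal")
        mask = roi_pixel_mask(roi, 128, 128)
        major, minor, center, angle = fit_ellipse(mask=mask)
        # pixelation biases the discrete-mask moments slightly (~1%)
        assert major == pytest.approx(60.0, rel=0.015)
        assert minor == pytest.approx(20.0, rel=0.015)
        assert min(angle, 180 - angle) < 1.0
        assert center[0] == pytest.approx(64.0, abs=0.2)

    def test_rotated_ellipse_points_within_1pct(self, rng):
        a, b, ang = 25.0, 12.0, 45.0
        t = rng.uniform(0, 2 * math.pi, 500)
        th = math.radians(ang)
        x = 100 + a * np.cos(t) * math.cos(th) - b * np.sin(t) * math.sin(th)
        y = 100 + a * np.cos(t) * math.sin(th) + b * np.sin(t) * math.cos(th)
        major, minor, _, angle = fit_ellipse(points=np.column_stack([x, y]))
        assert major == pytest.approx(2 * a, rel=0.01)
        assert minor == pytest.approx(2 * b, rel=0.01)
        assert angle == pytest.approx(ang, abs=1.0)

    def test_moment_fit_matches_regionprops(self, rng):
        """Cross-check the moment-equivalent ellipse against the standard
        regionprops implementation."""
        from skimage.measure import label, regionprops

        roi = Roi("e", EllipseShape(cx=60, cy=70, a=22, b=9, angle_deg=30),
                  "signal")
        mask = roi_pixel_mask(roi, 128, 128)
        major, minor, _, _ = fit_ellipse(mask=mask)
        props = regionprops(label(mask.astype(int)))[0]
        assert major == pytest.approx(props.axis_major_length, rel=1e-6)
        assert minor == pytest.approx(props.axis_minor_length, rel=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(points=np.array([[0, 0], [1, 1], [2, 2], [3, 3]]))
        collinear = np.zeros((64, 64), dtype=bool)
        collinear[10, 5:30] = True
        with pytest.raises(ValueError):
            fit_ellipse(mask=collinear)
        with pytest.raises(ValueError):
            fit_ellipse()


class TestCraterDiameter:
    @pytest.mark.parametrize("maj,mino,expected",
                             [(60, 20, 40), (35, 35, 35), (93, 93, 93)])
    def test_mean_of_axes(self, maj, mino, expected):
        assert crater_diameter(maj, mino) == pytest.approx(expected)

    def test_invalid_axes(self):
        with pytest.raises(ValueError):
            crater_diameter(10, 20)
        with pytest.raises(ValueError):
            crater_diameter(10, 0)


class TestParticleDiameter:
    def test_scalar_ratios(self):
        ident = ParticleCraterCalibration("al", 1.7, ratio=1.0)
        assert particle_diameter(40.0, ident) == pytest.approx(40.0)
        double = ParticleCraterCalibration("al", 1.7, ratio=2.0)
        assert particle_diameter(40.0, double) == pytest.approx(20.0)

    def test_table_interpolation(self):
        cal = ParticleCraterCalibration("al", 1.7,
                                        table=np.array([[10, 4], [100, 40]]))
        assert particle_diameter(55.0, cal) == pytest.approx(22.0)

    def test_out_of_table_clamped_with_warning(self):
        cal = ParticleCraterCalibration("al", 1.7,
                                        table=np.array([[10, 4], [100, 40]]))
        with pytest.warns(UserWarning, match="outside"):
            assert particle_diameter(500.0, cal) == pytest.approx(40.0)

    def test_invalid_calibrations_rejected(self):
        with pytest.raises(ValueError):
            ParticleCraterCalibration("al", 1.7)  # neither form
        with pytest.raises(ValueError):
            ParticleCraterCalibration("al", 1.7, ratio=2.0,
                                      table=np.array([[1, 1], [2, 2]]))
        with pytest.raises(ValueError, match="increasing"):
            ParticleCraterCalibration("al", 1.7,
                                      table=np.array([[10, 4], [5, 40]]))

    def test_json_roundtrip(self, tmp_path):
        for cal in (
            ParticleCraterCalibration("aluminium", 1.7, ratio=3.0),
            ParticleCraterCalibration("aluminium", 2.5,
                                      table=np.array([[10.0, 4.0], [100.0, 40.0]])),
        ):
            path = tmp_path / "pc.json"
            save_pc_calibration(cal, path)
            back = load_pc_calibration(path)
            assert back.target_material == cal.target_material
            assert back.velocity_km_s == cal.velocity_km_s
            assert back.ratio == cal.ratio
            if cal.table is not None:
                np.testing.assert_allclose(back.table, cal.table)


class TestImpactorPicomoles:
    def test_hand_case_16um(self):
        assert impactor_picomoles(16.0, 100.0) == pytest.approx(
            (math.pi / 6) * 4096 * 1e-7, rel=1e-12)
        assert impactor_picomoles(16.0, 100.0) == pytest.approx(2.145e-4, rel=1e-3)

    def test_zero_diameter(self):
        assert impactor_picomoles(0.0, 100.0) == 0.0

    def test_standard_concentration_reduction(self, rng):
        """General C-dependent form reduces to (pi/6) D^3 1e-7 at 100 µM."""
        for d in rng.uniform(0, 200, 1000):
            assert impactor_picomoles(d, 100.0) == pytest.approx(
                (math.pi / 6) * d**3 * 1e-7, rel=1e-14, abs=0.0)

    def test_sphere_droplet_identity(self, rng):
        """An impactor is just a droplet whose volume is the sphere volume."""
        for _ in range(200):
            d = rng.uniform(0.1, 150)
            c = rng.uniform(0.1, 500)
            sphere_nL = (math.pi / 6) * d**3 * 1e-6
            assert impactor_picomoles(d, c) == pytest.approx(
                droplet_picomoles(c, sphere_nL), rel=1e-14)

    def test_cubic_scaling(self, rng):
        for d in rng.uniform(1, 50, 20):
            assert impactor_picomoles(2 * d, 100.0) == pytest.approx(
                8 * impactor_picomoles(d, 100.0), rel=1e-12)


class TestCaptureEfficiency:
    def test_complete_capture(self):
        assert capture_efficiency(0.5, 0.5) == pytest.approx(100.0)

    def test_eleven_percent(self):
        assert capture_efficiency(0.055, 0.5) == pytest.approx(11.0)

    def test_empty_crater(self):
        assert capture_efficiency(0.0, 0.5) == 0.0

    def test_over_100_warned_not_clamped(self):
        with pytest.warns(UserWarning, match="exceeds 100"):
            assert capture_efficiency(1.0, 0.5) == pytest.approx(200.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            capture_efficiency(0.1, 0.0)
        with pytest.raises(ValueError):
            capture_efficiency(-0.1, 1.0)


def _crater_scene(pmol, a_px=30.0, b_px=27.0, angle=20.0, contrast=None,
                  seed=5, noise="none"):
    dep = Deposit("crater1", EllipseShape(100, 100, a_px, b_px, angle),
                  pmol, humidity_contrast=contrast)
    return SynthScene(width_px=200, height_px=200, deposits=[dep],
                      noise=noise, exposure_s=10.0, n_background_rois=3,
                      seed=seed)


def _run_analyze(scene, cal_fit, pc):
    rendered = render_scene(scene)
    crater_roi = next(r for r in rendered.rois if r.role == "signal")
    bgs = [r for r in rendered.rois if r.role == "background"]
    return analyze_crater(crater_roi, rendered.dry, rendered.humid, bgs,
                          cal_fit, pc)


class TestAnalyzeCrater:
    pc = ParticleCraterCalibration("aluminium", 1.7, ratio=3.0)
    # calibration consistent with the scene's emission constant
    cal = CalibrationFit(a=1e10, b=1.0, se_a=0, se_b=0, n_points=4,
                         domain_pmol=(1e-7, 1.0), objective="10x",
                         aggregation="mean-per-concentration")

    def test_closed_loop_recovery(self):
        """Noiseless synthetic crater recovers the deposited efficiency."""
        d_crater = (30.0 + 27.0)  # full axes mean, px = µm at 1 µm/px
        d_particle = d_crater / 3.0
        pmol_imp = impactor_picomoles(d_particle, 100.0)
        true_eff = 0.07
        rec = _run_analyze(_crater_scene(true_eff * pmol_imp), self.cal, self.pc)
        assert not rec.artifact_flag
        assert rec.crater_diameter_um == pytest.approx(d_crater, rel=0.01)
        assert rec.particle_diameter_um == pytest.approx(d_particle, rel=0.01)
        assert rec.capture_efficiency_pct == pytest.approx(100 * true_eff,
                                                           rel=0.05)

    def test_humidity_insensitive_residue_flagged(self):
        rec = _run_analyze(_crater_scene(1e-4, contrast=1.0), self.cal, self.pc)
        assert rec.artifact_flag
        assert rec.capture_efficiency_pct is None
        assert rec.crater_pmol is None
        assert rec.crater_diameter_um > 0  # geometry still reported

    def test_blank_crater_zero_efficiency(self):
        rec = _run_analyze(_crater_scene(0.0), self.cal, self.pc)
        assert not rec.artifact_flag
        assert rec.capture_efficiency_pct == 0.0

    def test_gain_invariance(self):
        """Scaling camera gain (pixel counts and the fit's a) together
        leaves the efficiency unchanged."""
        d_particle = 19.0
        pmol = 0.05 * impactor_picomoles(d_particle, 100.0)
        effs = []
        for gain in (1.0, 4.0):
            scene = _crater_scene(pmol)
            scene.brightness_per_pmol *= gain
            cal = CalibrationFit(a=1e10 * gain, b=1.0, se_a=0, se_b=0,
                                 n_points=4, domain_pmol=(1e-7, 1.0))
            effs.append(_run_analyze(scene, cal, self.pc).capture_efficiency_pct)
        assert effs[0] == pytest.approx(effs[1], rel=1e-3)
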