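"""Image/ROI I/O and ROI geometry."""

import math

import numpy as np
import pytest

from impactquant.imaging import (
    EllipseShape,
    ImagePlane,
    PolygonShape,
    Roi,
    blue_channel,
    read_rgb_image,
    read_roi_file,
    roi_area_um2,
    roi_mean_intensity,
    roi_pixel_mask,
    write_rgb_image,
    write_roi_file,
)

from conftest import ellipse_inside, random_star_polygon, ray_cast_inside


class TestImageIO:
    def test_rgb_split_constant_blue(self, tmp_path):
        arr = np.zeros((4, 4, 3), dtype=np.uint8)
        arr[:, :, 2] = 7
        import imageio.v3 as iio

        path = tmp_path / "img.png"
        iio.imwrite(path, arr)
        planes = read_rgb_image(path, exposure_s=1.0, pixel_size_um=1.0)
        assert [p.channel for p in planes] == ["red", "green", "blue"]
        blue = blue_channel(planes)
        assert blue.pixels.shape == (4, 4)
        assert np.all(blue.pixels == 7)

    def test_write_read_roundtrip_16bit(self, tmp_path, rng):
        arr = rng.integers(0, 65536, size=(16, 16, 3), dtype=np.uint16)
        planes = [
            ImagePlane(arr[:, :, i], bit_depth=16, channel=c,
                       exposure_s=2.0, pixel_size_um=0.5)
            for i, c in enumerate(("red", "green", "blue"))
        ]
        path = tmp_path / "img.tif"
        write_rgb_image(path, planes)
        back = read_rgb_image(path, exposure_s=2.0, pixel_size_um=0.5)
        for orig, rb in zip(planes, back):
            assert rb.bit_depth == 16
            np.testing.assert_array_equal(orig.pixels, rb.pixels)

    def test_channel_split_conserves_data(self, tmp_path, rng):
        """Recombining the R, G, B planes reproduces the source raster."""
        arr = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
        import imageio.v3 as iio

        path = tmp_path / "img.png"
        iio.imwrite(path, arr)
        planes = read_rgb_image(path, 1.0, 1.0)
        recombined = np.stack([p.pixels for p in planes], axis=-1)
        np.testing.assert_array_equal(recombined, arr)

    def test_grayscale_yields_mono(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "mono.png"
        iio.imwrite(path, np.full((5, 5), 9, dtype=np.uint8))
        planes = read_rgb_image(path, 1.0, 1.0)
        assert len(planes) == 1 and planes[0].channel == "mono"
        assert blue_channel(planes) is planes[0]

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(exposure_s=0.0, pixel_size_um=1.0), "exposure_s"),
            (dict(exposure_s=1.0, pixel_size_um=-2.0), "pixel_size_um"),
        ],
    )
    def test_bad_metadata_rejected(self, tmp_path, kwargs, msg):
        import imageio.v3 as iio

        path = tmp_path / "img.png"
        iio.imwrite(path, np.zeros((2, 2, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match=msg):
            read_rgb_image(path, **kwargs)

    def test_no_blue_plane_rejected(self, constant_plane):
        from dataclasses import replace

        red = replace(constant_plane(), channel="red")
        with pytest.raises(ValueError, match="blue"):
            blue_channel([red])

    def test_plane_value_range_enforced(self):
        with pytest.raises(ValueError, match="pixel values"):
            ImagePlane(np.array([[300]]), bit_depth=8, channel="mono",
                       exposure_s=1.0, pixel_size_um=1.0)


class TestPixelMask:
    def test_rectangle_covering_centres(self, square_roi):
        roi = square_roi(-0.5, -0.5, 10.0)
        mask = roi_pixel_mask(roi, 20, 20)
        assert mask.sum() == 100
        assert mask[:10, :10].all()

    def test_subpixel_circle_hits_single_centre(self):
        roi = Roi("dot", EllipseShape(cx=5.0, cy=5.0, a=0.4, b=0.4), "signal")
        mask = roi_pixel_mask(roi, 20, 20)
        assert mask.sum() == 1 and mask[5, 5]

    def test_roi_outside_image_rejected(self):
        roi = Roi("off", EllipseShape(cx=100.0, cy=100.0, a=3.0, b=3.0), "signal")
        with pytest.raises(ValueError, match="off"):
            roi_pixel_mask(roi, 20, 20)

    def test_polygon_mask_matches_ray_casting_oracle(self, rng):
        """Masks agree with a brute-force point-in-polygon scan of every
        pixel centre, over many random simple polygons."""
        for _ in range(60):
            shape = random_star_polygon(
                rng, cx=rng.uniform(15, 49), cy=rng.uniform(15, 49),
                r_min=2.0, r_max=13.0, n_vertices=int(rng.integers(3, 12)),
            )
            mask = roi_pixel_mask(Roi("p", shape, "signal"), 64, 64)
            oracle = np.zeros((64, 64), dtype=bool)
            for y in range(64):
                for x in range(64):
                    oracle[y, x] = ray_cast_inside(
                        shape.vertices, x + 1e-9, y + 1e-9
                    )
            np.testing.assert_array_equal(mask, oracle)

    def test_ellipse_mask_matches_quadratic_oracle(self, rng):
        for _ in range(40):
            shape = EllipseShape(
                cx=rng.uniform(15, 49), cy=rng.uniform(15, 49),
                a=rng.uniform(6, 13), b=rng.uniform(2, 6),
                angle_deg=rng.uniform(0, 180),
            )
            mask = roi_pixel_mask(Roi("e", shape, "signal"), 64, 64)
            oracle = np.zeros((64, 64), dtype=bool)
            for y in range(64):
                for x in range(64):
                    oracle[y, x] = ellipse_inside(shape, x + 1e-9, y + 1e-9)
            np.testing.assert_array_equal(mask, oracle)


class TestGeometry:
    def test_square_area_unit_and_half_pixel(self, square_roi):
        roi = square_roi(0, 0, 10.0)
        assert roi_area_um2(roi, 1.0) == pytest.approx(100.0)
        assert roi_area_um2(roi, 0.5) == pytest.approx(25.0)

    def test_ellipse_area_pi_ab(self):
        roi = Roi("e", EllipseShape(cx=0, cy=0, a=20, b=10), "signal")
        assert roi_area_um2(roi, 1.0) == pytest.approx(200 * math.pi)

    def test_area_matches_mask_count_for_large_shapes(self, rng):
        """Geometric area and mask-pixel area converge for big shapes."""
        for _ in range(10):
            a = rng.uniform(20, 30)
            b = rng.uniform(18, a)
            shape = EllipseShape(cx=64, cy=64, a=a, b=b,
                                 angle_deg=rng.uniform(0, 180))
            roi = Roi("e", shape, "signal")
            mask = roi_pixel_mask(roi, 128, 128)
            assert mask.sum() >= 1000
            geom = roi_area_um2(roi, 1.0)
            assert abs(geom - mask.sum()) / geom < 0.02

    def test_mean_intensity_constant_and_two_pixel(self, constant_plane):
        plane = constant_plane(50)
        roi = Roi("c", EllipseShape(cx=10, cy=10, a=4, b=4), "signal")
        assert roi_mean_intensity(plane, roi) == 50.0

        two = constant_plane(0)
        two.pixels[5, 5] = 10
        two.pixels[5, 6] = 30
        pair = Roi(
            "pair",
            PolygonShape(np.array([[4.6, 4.6], [6.4, 4.6], [6.4, 5.4], [4.6, 5.4]])),
            "signal",
        )
        assert roi_mean_intensity(two, pair) == 20.0

    def test_mean_matches_direct_sum_over_oracle_mask(self, rng):
        plane_px = rng.integers(0, 1000, size=(64, 64)).astype(np.uint16)
        plane = ImagePlane(plane_px, bit_depth=16, channel="blue",
                           exposure_s=1.0, pixel_size_um=1.0)
        shape = random_star_polygon(rng, 30, 30, 5, 18, 9)
        roi = Roi("p", shape, "signal")
        vals = [
            plane_px[y, x]
            for y in range(64)
            for x in range(64)
            if ray_cast_inside(shape.vertices, x + 1e-9, y + 1e-9)
        ]
        assert roi_mean_intensity(plane, roi) == pytest.approx(np.mean(vals))

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            PolygonShape(np.array([[0, 0], [1, 1], [2, 2]]))  # collinear

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ValueError, match="simple"):
            PolygonShape(np.array([[0, 0], [2, 2], [2, 0], [0, 2]]))

    def test_ellipse_axis_order_enforced(self):
        with pytest.raises(ValueError):
            EllipseShape(cx=0, cy=0, a=1.0, b=2.0)


class TestRoiFiles:
    def _rois(self):
        return [
            Roi("sig", EllipseShape(cx=10.5, cy=11.25, a=5.0, b=3.0,
                                    angle_deg=30.0), "signal"),
            Roi("bg1", PolygonShape(np.array([[0.0, 0.0], [4.0, 0.5],
                                              [3.5, 4.0]])), "background"),
            Roi("bg2", EllipseShape(cx=20, cy=20, a=2, b=2), "background"),
        ]

    def test_roundtrip_preserves_everything(self, tmp_path):
        path = tmp_path / "rois.json"
        write_roi_file(self._rois(), path)
        back = read_roi_file(path)
        assert [r.label for r in back] == ["sig", "bg1", "bg2"]
        assert [r.role for r in back] == ["signal", "background", "background"]
        assert back[0].shape.angle_deg == pytest.approx(30.0, rel=1e-9)
        np.testing.assert_allclose(
            back[1].shape.vertices, self._rois()[1].shape.vertices, rtol=1e-9
        )

    def test_large_polygon_roundtrip(self, tmp_path, rng):
        t = np.linspace(0, 2 * math.pi, 1000, endpoint=False)
        r = 50 + rng.uniform(-3, 3, 1000)
        verts = np.column_stack([100 + r * np.cos(t), 100 + r * np.sin(t)])
        roi = Roi("big", PolygonShape(verts), "signal")
        path = tmp_path / "big.json"
        write_roi_file([roi], path)
        back = read_roi_file(path)
        np.testing.assert_allclose(back[0].shape.vertices, verts, rtol=1e-9)

    def test_missing_role_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(
            '{"rois":[{"label":"x","shape":{"type":"ellipse",'
            '"cx":1,"cy":1,"a":2,"b":1}}]}'
        )
        with pytest.raises(ValueError, match="role"):
            read_roi_file(path)

    def test_missing_shape_field_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"rois":[{"label":"x","role":"signal",'
                        '"shape":{"type":"ellipse","cx":1}}]}')
        with pytest.raises(ValueError, match="missing"):
            read_roi_file(path)
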