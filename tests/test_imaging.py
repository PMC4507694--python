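"""Image I/O and half-radius spot sampling."""

import math

import numpy as np
import pytest
from PIL import Image

from stripquant import (
    KineticParams,
    RGBImage,
    SimulationConfig,
    SpotROI,
    detect_spots,
    load_image,
    render_series,
    sample_spot_color,
    save_image,
    tone_values,
)
from stripquant.errors import (
    DetectionError,
    GeometryError,
    InputError,
)
from stripquant.imaging import read_readings_csv, readings_to_frame, write_readings_csv

from conftest import uniform_image


class TestLoadImage:
    def test_png_round_trip_identity(self, tmp_path):
        px = np.empty((4, 4, 3), dtype=np.uint8)
        px[:] = (10, 20, 30)
        Image.fromarray(px).save(tmp_path / "a.png")
        img = load_image(tmp_path / "a.png")
        assert img.width == img.height == 4
        assert (img.pixels == [10, 20, 30]).all()

    def test_grayscale_replicated_across_channels(self, tmp_path):
        Image.fromarray(np.full((2, 2), 128, dtype=np.uint8), mode="L").save(
            tmp_path / "g.png"
        )
        img = load_image(tmp_path / "g.png")
        assert (img.pixels == 128).all()

    def test_alpha_discarded(self, tmp_path):
        px = np.zeros((3, 3, 4), dtype=np.uint8)
        px[..., :3] = (5, 6, 7)
        px[..., 3] = 200
        Image.fromarray(px, mode="RGBA").save(tmp_path / "a.png")
        img = load_image(tmp_path / "a.png")
        assert img.pixels.shape == (3, 3, 3)
        assert (img.pixels == [5, 6, 7]).all()

    def test_16bit_reduced_by_integer_division(self, tmp_path):
        arr = np.full((2, 2), 33000, dtype=np.uint16)
        Image.fromarray(arr).save(tmp_path / "w.png")
        img = load_image(tmp_path / "w.png")
        assert (img.pixels == 33000 // 256).all()

    def test_uniform_jpeg_survives_compression(self, tmp_path):
        # A constant field has no high-frequency content, so lossy JPEG
        # reconstructs it exactly: write-then-read oracle.
        px = np.full((16, 16, 3), 100, dtype=np.uint8)
        Image.fromarray(px).save(tmp_path / "u.jpg", quality=95)
        img = load_image(tmp_path / "u.jpg")
        assert (img.pixels == 100).all()

    def test_missing_file_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            load_image(tmp_path / "nope.png")

    def test_undecodable_file_is_format_error(self, tmp_path):
        (tmp_path / "junk.png").write_bytes(b"this is not an image")
        with pytest.raises(InputError):
            load_image(tmp_path / "junk.png")


def test_tone_values_per_bit_depth():
    assert tone_values(8) == 256
    assert tone_values(12) == 4096
    assert tone_values(16) == 65536
    with pytest.raises(InputError):
        tone_values(0)


class TestSampleSpotColor:
    @pytest.mark.parametrize("mode,n_points", [("point", 1), ("ring", 1),
                                               ("ring", 8), ("ring", 17)])
    def test_uniform_image_returns_uniform_color(self, mode, n_points):
        img = uniform_image()
        roi = SpotROI(16, 12, 8, "u")
        rd = sample_spot_color(img, roi, mode=mode, n_points=n_points)
        assert (rd.r, rd.g, rd.b) == (100, 150, 200)

    def test_point_reads_pixel_at_half_radius_right_of_center(self):
        img = uniform_image(32, 24, (50, 50, 50))
        px = img.pixels.copy()
        px[12, 20] = (7, 8, 9)  # (cx + r/2, cy) = (16 + 4, 12)
        img = RGBImage(px)
        rd = sample_spot_color(img, SpotROI(16, 12, 8, "p"), mode="point")
        assert (rd.r, rd.g, rd.b) == (7, 8, 9)

    def test_ring_one_point_equals_point_mode(self):
        rng = np.random.default_rng(0)
        img = RGBImage(rng.integers(0, 256, (24, 32, 3), dtype=np.uint8))
        roi = SpotROI(16, 12, 8, "x")
        a = sample_spot_color(img, roi, mode="point")
        b = sample_spot_color(img, roi, mode="ring", n_points=1)
        assert (a.r, a.g, a.b) == (b.r, b.g, b.b)

    def test_ring_average_matches_brute_force_oracle(self):
        # Independent oracle: recompute the nearest-pixel ring average
        # directly, with half-up rounding.
        rng = np.random.default_rng(42)
        img = RGBImage(rng.integers(0, 256, (40, 40, 3), dtype=np.uint8))
        roi = SpotROI(20, 20, 12, "o")
        n = 8
        pts = []
        for j in range(n):
            ang = 2 * math.pi * j / n
            pts.append((int(round(20 + 6 * math.cos(ang))),
                        int(round(20 + 6 * math.sin(ang)))))
        expect = [
            math.floor(np.mean([img.pixels[y, x, c] for x, y in pts]) + 0.5)
            for c in range(3)
        ]
        rd = sample_spot_color(img, roi, mode="ring", n_points=n)
        assert [rd.r, rd.g, rd.b] == expect

    def test_same_locus_two_code_paths_agree(self):
        # Reading the same pixels through the point path and a 1-point
        # ring must give identical color codes (the cross-software
        # reproducibility property of digital color readout).
        rng = np.random.default_rng(3)
        img = RGBImage(rng.integers(0, 256, (30, 30, 3), dtype=np.uint8))
        for cx in (10, 15, 20):
            roi = SpotROI(cx, 15, 6, "c")
            a = sample_spot_color(img, roi, mode="point")
            b = sample_spot_color(img, roi, mode="ring", n_points=1)
            assert (a.r, a.g, a.b) == (b.r, b.g, b.b)

    def test_locus_outside_image_is_geometry_error(self):
        img = uniform_image(10, 10)
        with pytest.raises(GeometryError):
            sample_spot_color(img, SpotROI(9, 5, 6, "edge"))

    def test_values_survive_png_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        img = RGBImage(rng.integers(0, 256, (24, 32, 3), dtype=np.uint8))
        roi = SpotROI(16, 12, 8, "rt")
        before = sample_spot_color(img, roi)
        save_image(img, tmp_path / "rt.png")
        after = sample_spot_color(load_image(tmp_path / "rt.png"), roi)
        assert (before.r, before.g, before.b) == (after.r, after.g, after.b)

    def test_noise_free_render_matches_manifest_color(self):
        cfg = SimulationConfig(
            activities=[2.73e-5], replicates=1,
            pixel_noise_sd=0, replicate_noise_sd=0, seed=5,
        )
        images, man = render_series(cfg)
        spot = man.spot("lvl00", 0)
        roi = man.rois()[0]
        for t in (0.0, 30.0, 60.0):
            rd = sample_spot_color(images[(t, 0)], roi)
            expect = [math.floor(v + 0.5) for v in spot.colors[t]]
            assert [rd.r, rd.g, rd.b] == expect

    def test_radius_below_two_rejected(self):
        with pytest.raises(InputError):
            SpotROI(5, 5, 1.5, "tiny")


class TestDetectSpots:
    def _disk_image(self, centers, radius=8, w=120, h=40):
        px = np.full((h, w, 3), (235, 232, 225), dtype=np.uint8)
        yy, xx = np.mgrid[0:h, 0:w]
        for cx, cy in centers:
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
            px[mask] = (41, 120, 100)
        return RGBImage(px)

    def test_single_disk_recovered(self):
        img = self._disk_image([(30, 20)], radius=8)
        rois = detect_spots(img, expected_n=1, min_radius=3)
        assert len(rois) == 1
        assert abs(rois[0].center_x - 30) <= 1
        assert abs(rois[0].center_y - 20) <= 1
        assert abs(rois[0].radius - 8) <= 0.8

    def test_blank_background_is_detection_error(self):
        img = self._disk_image([])
        with pytest.raises(DetectionError):
            detect_spots(img, expected_n=1, min_radius=3)

    def test_two_disks_ordered_left_to_right(self):
        img = self._disk_image([(90, 20), (30, 20)], radius=8)
        rois = detect_spots(img, expected_n=2, min_radius=3)
        assert len(rois) == 2
        assert rois[0].center_x < rois[1].center_x
        assert abs(rois[0].center_x - 30) <= 1
        assert abs(rois[1].center_x - 90) <= 1


def test_readings_csv_round_trip(tmp_path):
    from stripquant import ColorReading

    readings = [
        ColorReading(r=10, g=20, b=30, time_min=0, label="s1"),
        ColorReading(r=11, g=21, b=31, time_min=30, label="s1"),
    ]
    rois = [SpotROI(16, 12, 8, "s1")]
    frame = readings_to_frame(readings, rois)
    write_readings_csv(frame, tmp_path / "r.csv")
    back = read_readings_csv(tmp_path / "r.csv")
    assert list(back["r"]) == [10, 11]
    assert list(back["time_min"]) == [0, 30]
    assert (back["radius"] == 8).all()
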