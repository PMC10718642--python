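"""Detector geometry: q/phi mapping, cake binning, and image round trips."""

import json

import numpy as np
import pytest

from discsaxs.geometry import (
    DetectorGeometry,
    DetectorImage,
    cake_bins,
    pixel_to_q_phi,
    q_phi_maps,
    read_image,
    write_image,
)


class TestPixelToQPhi:
    def test_beam_center_is_q_zero_with_undefined_phi(self, geometry):
        q, phi = pixel_to_q_phi(geometry, geometry.beam_center)
        assert q == 0.0
        assert np.isnan(phi)

    def test_wavelength_at_10_kev(self, geometry):
        assert geometry.wavelength_nm == pytest.approx(0.1239842, rel=1e-6)

    def test_q_linear_in_radius_at_small_angle(self, geometry):
        cx, cy = geometry.beam_center
        q1, _ = pixel_to_q_phi(geometry, (cx + 20, cy))
        q2, _ = pixel_to_q_phi(geometry, (cx + 40, cy))
        assert q2 / q1 == pytest.approx(2.0, rel=1e-3)

    def test_phi_folded_into_half_circle(self, geometry):
        cx, cy = geometry.beam_center
        _, phi_right = pixel_to_q_phi(geometry, (cx + 30, cy))
        _, phi_left = pixel_to_q_phi(geometry, (cx - 30, cy))
        assert phi_right == pytest.approx(0.0, abs=1e-9)
        assert phi_left == pytest.approx(0.0, abs=1e-9)  # Friedel fold
        _, phi_up = pixel_to_q_phi(geometry, (cx, cy - 30))  # up on screen
        assert phi_up == pytest.approx(90.0, abs=1e-9)

    def test_maps_match_scalar_function(self, geometry):
        q_map, phi_map = q_phi_maps(geometry)
        q, phi = pixel_to_q_phi(geometry, (10, 200))
        assert q_map[200, 10] == pytest.approx(q, rel=1e-12)
        assert phi_map[200, 10] == pytest.approx(phi, rel=1e-12)


class TestCakeBins:
    def test_single_bin_collects_all_in_range_pixels(self, geometry):
        bins = cake_bins(geometry, (0.02, 0.12), 1, (0.0, 180.0), 1)
        q_map, phi_map = q_phi_maps(geometry)
        expected = ((q_map >= 0.02) & (q_map < 0.12) & np.isfinite(phi_map)).sum()
        assert bins["pixels_per_bin"].sum() == expected

    def test_partition_conserves_pixel_count(self, geometry):
        bins = cake_bins(geometry, (0.03, 0.10), 7, (0.0, 180.0), 13)
        n_pixels = np.prod(geometry.image_shape)
        assert bins["pixels_per_bin"].sum() + bins["n_out_of_range"] == n_pixels
        # no index appears outside [-1, n_bins)
        assert bins["bin_index"].max() < 7 * 13
        assert bins["bin_index"].min() >= -1

    def test_ten_degree_sectors_make_18_bins(self, geometry):
        bins = cake_bins(geometry, (0.05, 0.15), 1, (0.0, 180.0), 18)
        assert bins["n_phi"] == 18
        assert np.all(np.diff(bins["phi_edges"]) == pytest.approx(10.0))

    def test_empty_range_rejected(self, geometry):
        with pytest.raises(ValueError):
            cake_bins(geometry, (0.12, 0.02), 5, (0.0, 180.0), 5)


class TestImageIO:
    def test_write_read_round_trip(self, tmp_path, geometry):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=geometry.image_shape).astype(np.float64)
        img = DetectorImage(counts=counts, geometry=geometry, frame_index=3, time_s=9.0)
        path = write_image(tmp_path / "f.tif", img)
        back = read_image(path)
        np.testing.assert_array_equal(back.counts, counts)
        assert back.geometry == geometry
        assert back.frame_index == 3
        assert back.time_s == 9.0

    def test_missing_sidecar_is_an_error(self, tmp_path, geometry):
        img = DetectorImage(np.zeros(geometry.image_shape), geometry)
        path = write_image(tmp_path / "f.tif", img)
        path.with_suffix(".geom.json").unlink()
        with pytest.raises(FileNotFoundError):
            read_image(path)

    def test_sidecar_missing_field_named_in_error(self, tmp_path, geometry):
        img = DetectorImage(np.zeros(geometry.image_shape), geometry)
        path = write_image(tmp_path / "f.tif", img)
        sc = path.with_suffix(".geom.json")
        d = json.loads(sc.read_text())
        del d["distance_mm"]
        sc.write_text(json.dumps(d))
        with pytest.raises(ValueError, match="distance_mm"):
            read_image(path)

    def test_negative_pixels_are_masked(self, geometry):
        counts = np.ones(geometry.image_shape)
        counts[5, 5] = -1
        img = DetectorImage(counts, geometry)
        assert not img.mask[5, 5]
        assert img.mask.sum() == counts.size - 1


def test_geometry_validation_rejects_nonpositive_lengths():
    with pytest.raises(ValueError):
        DetectorGeometry((10, 10), pixel_size_mm=-0.1, distance_mm=1000.0)
    with pytest.raises(ValueError):
        DetectorGeometry((10, 10), pixel_size_mm=0.1, distance_mm=0.0)


def test_rendered_peak_maps_back_to_its_coordinates(geometry, scatter, noiseless_frame):
    """A peak rendered at (q0, phi0) lands in the right (q, phi) bin."""
    q_map, phi_map = q_phi_maps(geometry)
    masked = noiseless_frame.counts.copy()
    # restrict to the collagen-peak search range: below it the power-law
    # background near the beamstop dominates by construction
    masked[~noiseless_frame.mask | (q_map < 0.05) | (q_map > 0.15)] = 0.0
    ij = np.unravel_index(np.argmax(masked), masked.shape)
    q0 = scatter.q_peak_at(0.0)
    assert q_map[ij] == pytest.approx(q0, abs=0.0015)  # within a q-bin width
    d1 = abs(phi_map[ij] - 41.5)
    d2 = abs(phi_map[ij] - 138.5)
    assert min(d1, d2) < 2.0
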