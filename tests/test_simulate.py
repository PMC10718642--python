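"""Forward simulator: render contracts, series protocol, presets, speckle."""

import numpy as np
import pytest

from discsaxs.pipeline import analyze_frame
from discsaxs.simulate import (
    CompressionProtocol,
    FiberScatterParams,
    SyntheticSpecimen,
    UnreachableTargetError,
    diabetic_preset,
    frame_strains,
    lean_preset,
    render_pattern,
    simulate_load_trace,
    simulate_series,
    simulate_speckle_pair,
)


class TestRenderPattern:
    def test_same_seed_gives_identical_images(self, geometry, scatter):
        a = render_pattern(geometry, scatter, 97.0, 0.0, 0.005, 0.55, seed=7)
        b = render_pattern(geometry, scatter, 97.0, 0.0, 0.005, 0.55, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_different_seeds_differ(self, geometry, scatter):
        a = render_pattern(geometry, scatter, 97.0, 0.0, 0.005, 0.55, seed=7)
        b = render_pattern(geometry, scatter, 97.0, 0.0, 0.005, 0.55, seed=8)
        assert not np.array_equal(a.counts, b.counts)

    def test_peak_q_ratio_under_strain(self, scatter):
        # q = 2 pi n / d: 2% fibril strain scales peak position by 1/1.02
        assert scatter.q_peak_at(2.0) / scatter.q_peak_at(0.0) == pytest.approx(1 / 1.02)

    def test_unloaded_arcs_at_41p5_and_138p5(self, noiseless_frame):
        rec = analyze_frame(noiseless_frame)
        assert rec["center1_deg"] == pytest.approx(41.5, abs=0.2)
        assert rec["center2_deg"] == pytest.approx(138.5, abs=0.2)

    def test_photon_count_scaling(self, geometry):
        lo = FiberScatterParams(exposure_counts=1e5)
        hi = FiberScatterParams(exposure_counts=1e6)
        a = render_pattern(geometry, lo, 97.0, 0.0, 0.005, 0.55, seed=1)
        b = render_pattern(geometry, hi, 97.0, 0.0, 0.005, 0.55, seed=1)
        ta, tb = a.counts[a.mask].sum(), b.counts[b.mask].sum()
        # Poisson relative error ~ 1/sqrt(1e5) ~ 0.3%
        assert tb / ta == pytest.approx(10.0, rel=0.02)

    def test_unreachable_alignment_raises(self, geometry, scatter):
        with pytest.raises(UnreachableTargetError):
            render_pattern(geometry, scatter, 97.0, 0.0, 0.005, alignment_target=0.9999)

    def test_invalid_angle_rejected(self, geometry, scatter):
        with pytest.raises(ValueError):
            render_pattern(geometry, scatter, 0.0, 0.0, 0.005, 0.55)


class TestSimulateSeries:
    def test_default_protocol_gives_15_frames(self):
        eps = frame_strains(lean_preset())
        assert eps.size == 15
        np.testing.assert_allclose(eps[:3], [0.0, 0.75, 1.5])
        assert eps[-1] == 10.0

    def test_zero_max_strain_gives_single_frame(self):
        proto = CompressionProtocol(
            angle_trajectory=lambda e: 97.0,
            fibril_strain_trajectory=lambda e: 0.0,
            fwhm_trajectory=lambda e: 0.005,
            alignment_trajectory=lambda e: 0.55,
            stress_trajectory=lambda e: 0.0,
            max_applied_strain=0.0,
        )
        assert frame_strains(proto).size == 1

    def test_series_reproducible_and_truth_table_consistent(self, geometry):
        spec = SyntheticSpecimen("s1", "lean", lean_preset(), rng_seed=11)
        imgs1, truth1 = simulate_series(spec, geometry)
        imgs2, truth2 = simulate_series(spec, geometry)
        np.testing.assert_array_equal(imgs1[3].counts, imgs2[3].counts)
        assert truth1.equals(truth2)
        assert truth1["true_fibril_strain_pct"].iloc[-1] == pytest.approx(2.0)

    def test_load_trace_spans_all_exposures(self):
        spec = SyntheticSpecimen("s1", "lean", lean_preset(), rng_seed=0)
        trace = simulate_load_trace(spec)
        t_last = frame_strains(spec.protocol)[-1] / spec.protocol.strain_rate
        assert trace["time_s"].iloc[-1] >= t_last + spec.protocol.exposure_time


class TestPresets:
    """Trajectory endpoints are inputs to the simulator, guarded as regressions."""

    def test_lean_angle_increase_26_degrees(self):
        p = lean_preset()
        assert p.angle_trajectory(0) == pytest.approx(97.0)
        assert p.angle_trajectory(10) - p.angle_trajectory(0) == pytest.approx(26.0)

    def test_diabetic_angle_increase_18_degrees(self):
        p = diabetic_preset()
        assert p.angle_trajectory(0) == pytest.approx(97.0)
        assert p.angle_trajectory(10) - p.angle_trajectory(0) == pytest.approx(18.0)

    def test_both_groups_gain_10_degrees_by_3_percent(self):
        for p in (lean_preset(), diabetic_preset()):
            assert p.angle_trajectory(3) - p.angle_trajectory(0) == pytest.approx(10.0)

    def test_fibril_strain_endpoints(self):
        assert lean_preset().fibril_strain_trajectory(10) == pytest.approx(2.0)
        assert diabetic_preset().fibril_strain_trajectory(10) == pytest.approx(1.4)

    def test_diabetic_fwhm_broadens_only_above_4_percent(self):
        p = diabetic_preset()
        assert p.fwhm_trajectory(2.0) == pytest.approx(p.fwhm_trajectory(0.0), rel=1e-6)
        assert p.fwhm_trajectory(10.0) > 1.1 * p.fwhm_trajectory(0.0)

    def test_diabetic_alignment_declines_after_8_percent(self):
        p = diabetic_preset()
        assert p.alignment_trajectory(10.0) < p.alignment_trajectory(8.0)
        assert lean_preset().alignment_trajectory(10.0) > lean_preset().alignment_trajectory(8.0)

    def test_angle_trajectories_monotone(self):
        eps = np.linspace(0, 10, 101)
        for p in (lean_preset(), diabetic_preset()):
            angles = np.array([p.angle_trajectory(e) for e in eps])
            assert np.all(np.diff(angles) >= -1e-9)


class TestSpecklePair:
    def test_zero_strain_zero_shift_identical(self):
        ref, dfm = simulate_speckle_pair((100, 60), 150, 0.0, 0.0, seed=1)
        np.testing.assert_array_equal(ref, dfm)

    def test_pure_translation_preserves_content(self):
        ref, dfm = simulate_speckle_pair((100, 60), 150, 0.0, 5.0, seed=1)
        # shifted field equals reference away from boundaries
        np.testing.assert_allclose(dfm[10:90], ref[5:85], atol=1e-10)

    def test_seeded_reproducibility(self):
        a = simulate_speckle_pair((80, 50), 100, 3.0, 1.0, seed=9)
        b = simulate_speckle_pair((80, 50), 100, 3.0, 1.0, seed=9)
        np.testing.assert_array_equal(a[1], b[1])

    def test_zero_speckles_warns_and_returns_flat(self):
        with pytest.warns(UserWarning, match="textureless"):
            ref, _ = simulate_speckle_pair((50, 40), 0, 0.0, 0.0, seed=0)
        assert ref.std() == 0.0

    def test_negative_strain_rejected(self):
        with pytest.raises(ValueError):
            simulate_speckle_pair((50, 40), 10, -1.0, 0.0, seed=0)
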