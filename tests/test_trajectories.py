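"""Trajectory assembly, group difference curves, and summary metrics."""

import numpy as np
import pandas as pd
import pytest

from discsaxs.trajectories import (
    group_difference_curves,
    percent_difference,
    summarize_specimen,
)


def _series(specimen_id, group, angle_fn, fibril_fn, strains=None):
    strains = np.linspace(0, 10, 15) if strains is None else np.asarray(strains)
    return pd.DataFrame(
        {
            "specimen_id": specimen_id,
            "group": group,
            "applied_strain_pct": strains,
            "angle_deg": [angle_fn(e) for e in strains],
            "fibril_strain_pct": [fibril_fn(e) for e in strains],
            "qc_flag": "",
        }
    )


class TestSummarizeSpecimen:
    def test_lean_style_endpoints(self):
        s = summarize_specimen(_series("a", "lean", lambda e: 97 + 2.6 * e, lambda e: 0.2 * e))
        assert s["angle_increase_deg"] == pytest.approx(26.0)
        assert s["fibril_strain_pct"] == pytest.approx(2.0)
        assert s["transfer_fraction_pct"] == pytest.approx(20.0)
        assert s["angular_rate_deg_per_pct"] == pytest.approx(2.6)
        assert not s["partial"]

    def test_constant_angle_gives_zero_increase(self):
        s = summarize_specimen(_series("a", "lean", lambda e: 97.0, lambda e: 0.0))
        assert s["angle_increase_deg"] == pytest.approx(0.0)

    def test_interpolates_between_frames(self):
        # no frame at exactly 10%: 9.6 and 10.4 bracket it
        strains = np.array([0.0, 5.0, 9.6, 10.4])
        s = summarize_specimen(_series("a", "lean", lambda e: 97 + e, lambda e: 0.1 * e, strains))
        assert s["angle_increase_deg"] == pytest.approx(10.0)

    def test_truncated_series_flagged_partial(self):
        strains = np.linspace(0, 7, 8)
        s = summarize_specimen(_series("a", "lean", lambda e: 97 + e, lambda e: 0.1 * e, strains))
        assert s["partial"]
        assert s["eval_strain_pct"] == pytest.approx(7.0)

    def test_qc_flagged_frames_excluded(self):
        df = _series("a", "lean", lambda e: 97 + e, lambda e: 0.1 * e)
        df.loc[7, "angle_deg"] = 1e6
        df.loc[7, "qc_flag"] = "arc_fit: failed"
        s = summarize_specimen(df)
        assert s["angle_increase_deg"] == pytest.approx(10.0)


def _cohort(group, n, angle_offset=0.0, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n):
        jitter = rng.normal(0, 0.3)
        frames.append(
            _series(
                f"{group}_{i}",
                group,
                lambda e, j=jitter: 97 + (2.0 + angle_offset / 10) * e + j,
                lambda e: 0.15 * e,
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestGroupDifferenceCurves:
    def test_identical_groups_difference_zero_ci_covers_zero(self):
        lean = _cohort("lean", 5, seed=1)
        diab = _cohort("diabetic", 5, seed=1)
        # same generative process, same draws except labels
        df = pd.concat([lean, diab], ignore_index=True)
        gc = group_difference_curves(df, "angle_deg", n_boot=500, seed=3)
        assert np.nanmax(np.abs(gc.difference)) < 1.0
        assert np.all(gc.ci_low <= gc.difference + 1e-9)
        assert np.all(gc.ci_high >= gc.difference - 1e-9)

    def test_label_swap_negates_difference(self):
        df = pd.concat(
            [_cohort("lean", 4, seed=1), _cohort("diabetic", 4, angle_offset=-8, seed=2)],
            ignore_index=True,
        )
        gc = group_difference_curves(df, "angle_deg", n_boot=100, seed=5)
        swapped = df.copy()
        swapped["group"] = swapped["group"].map({"lean": "diabetic", "diabetic": "lean"})
        gc_sw = group_difference_curves(swapped, "angle_deg", n_boot=100, seed=5)
        np.testing.assert_allclose(gc_sw.difference, -gc.difference, atol=1e-12)

    def test_same_seed_reproduces_bands(self):
        df = pd.concat(
            [_cohort("lean", 4, seed=1), _cohort("diabetic", 4, angle_offset=-8, seed=2)],
            ignore_index=True,
        )
        a = group_difference_curves(df, "angle_deg", n_boot=200, seed=9)
        b = group_difference_curves(df, "angle_deg", n_boot=200, seed=9)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)

    def test_identical_group_band_rarely_excludes_zero(self):
        """Bootstrap sanity: under no true difference, the 95% band should
        exclude zero at only a small fraction of grid points."""
        excl = []
        for seed in range(10):
            df = pd.concat(
                [_cohort("lean", 6, seed=seed), _cohort("diabetic", 6, seed=100 + seed)],
                ignore_index=True,
            )
            gc = group_difference_curves(df, "angle_deg", n_boot=400, seed=seed)
            excl.append(np.mean((gc.ci_low > 0) | (gc.ci_high < 0)))
        assert np.mean(excl) < 0.15

    def test_missing_outcome_rejected(self):
        df = _cohort("lean", 3)
        with pytest.raises(ValueError):
            group_difference_curves(df, "nope")

    def test_too_few_specimens_rejected(self):
        df = pd.concat(
            [_cohort("lean", 1, seed=1), _cohort("diabetic", 3, seed=2)], ignore_index=True
        )
        with pytest.raises(ValueError, match="lean"):
            group_difference_curves(df, "angle_deg")


class TestPercentDifference:
    def test_age_cross_link_means(self):
        raw, rounded = percent_difference(237.0, 310.0)
        assert rounded == 31
        assert raw == pytest.approx(100 * 73 / 237)

    def test_fibril_strain_reduction(self):
        assert percent_difference(2.0, 1.4)[1] == -30

    def test_equal_means_zero(self):
        assert percent_difference(5.5, 5.5)[0] == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)
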