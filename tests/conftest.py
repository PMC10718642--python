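"""Shared fixtures: geometry, rendered frames, and analyzed cohorts.

The expensive simulated cohorts are session-scoped so the cohort-level
recovery checks and the trajectory statistics share one computation.
"""

from __future__ import annotations

import pandas as pd
import pytest

from discsaxs.geometry import default_geometry
from discsaxs.pipeline import analyze_series
from discsaxs.simulate import FiberScatterParams, make_cohort, render_pattern, simulate_series


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def scatter():
    return FiberScatterParams()


@pytest.fixture(scope="session")
def noiseless_frame(geometry, scatter):
    """Unloaded-state render without counting noise."""
    return render_pattern(
        geometry, scatter, interlamellar_angle=97.0, fibril_strain=0.0,
        fwhm_target=0.005, alignment_target=0.55, seed=None,
    )


def _analyze_cohort(group: str, n: int, base_seed: int) -> pd.DataFrame:
    tables = []
    for spec in make_cohort(group, n, base_seed=base_seed):
        images, truth = simulate_series(spec)
        tables.append(
            analyze_series(
                images,
                truth["applied_strain_pct"].to_numpy(),
                specimen_id=spec.specimen_id,
                group=spec.group,
            )
        )
    return pd.concat(tables, ignore_index=True)


@pytest.fixture(scope="session")
def cohort_measurements():
    """Full-pipeline measurements for 7 lean + 6 diabetic simulated discs."""
    lean = _analyze_cohort("lean", 7, base_seed=1)
    diab = _analyze_cohort("diabetic", 6, base_seed=101)
    return pd.concat([lean, diab], ignore_index=True)
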