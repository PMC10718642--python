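"""Whole-disc (macroscale) mechanics: speckle DIC strain and stress.

Applied compressive strain is measured from visible-light images of the
India-ink speckle pattern with a 1D digital image correlation scheme: the
image is cut into axial strips, each strip's axial displacement is found by
normalized cross-correlation with sub-pixel parabolic refinement, and the
axial strain is the (negated) least-squares slope of displacement vs axial
position — so compression is reported positive.  Stress comes from the load
cell divided by the radiograph-derived circular cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

__all__ = [
    "LoadTrace",
    "FrameMechanics",
    "DICError",
    "dic_axial_strain",
    "stress_from_load",
    "synchronize_frames",
]


class DICError(RuntimeError):
    """Raised when the speckle images cannot support a strain measurement."""


@dataclass
class LoadTrace:
    """Time-synchronized load-cell record from the testing stage."""

    time_s: np.ndarray
    force_n: np.ndarray
    displacement_mm: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "LoadTrace":
        df = pd.read_csv(path)
        return cls(
            time_s=df["time_s"].to_numpy(),
            force_n=df["force_N"].to_numpy(),
            displacement_mm=df["displacement_mm"].to_numpy(),
        )


@dataclass
class FrameMechanics:
    """One exposure's macroscale state (compression positive)."""

    frame_index: int
    applied_strain_pct: float
    stress_mpa: float
    force_n: float = float("nan")
    displacement_mm: float = float("nan")


def _ncc_axial_shift(ref_strip: np.ndarray, def_strip: np.ndarray, max_shift: int) -> tuple[float, float]:
    """Axial displacement u of def_strip relative to ref_strip by NCC.

    Correlates the full 2D strips over integer axial lags only (the whole
    lateral extent contributes texture, which suppresses false matches), then
    refines the argmax with a parabolic fit through its two neighbors.  Sign
    convention: deformed(y) ~ reference(y - u), so u < 0 where material has
    moved toward smaller row indices.  Returns (u_px, peak_correlation).
    """
    a = ref_strip
    b = def_strip
    n = a.shape[0]
    lags = np.arange(-max_shift, max_shift + 1)
    cc = np.full(lags.size, -np.inf)
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = a[: n - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: n + lag]
        if x.shape[0] < 8:
            continue
        xs = x - x.mean()
        ys = y - y.mean()
        denom = np.sqrt((xs**2).sum() * (ys**2).sum())
        if denom <= 0:
            continue
        cc[i] = float((xs * ys).sum() / denom)
    # b(y) ~ a(y - u): comparing a[j] with b[j + lag] peaks at lag = u
    i0 = int(np.argmax(cc))
    peak = cc[i0]
    u = float(lags[i0])
    if 0 < i0 < lags.size - 1 and np.isfinite(cc[i0 - 1]) and np.isfinite(cc[i0 + 1]):
        y0, y1, y2 = cc[i0 - 1], cc[i0], cc[i0 + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            u += 0.5 * (y0 - y2) / denom
    return u, float(peak)


def _strip_displacements(
    reference: np.ndarray,
    deformed: np.ndarray,
    n_strips: int,
    strip_overlap: float,
    max_shift: int,
    min_correlation: float,
) -> pd.DataFrame:
    nrow = reference.shape[0]
    strip_h = int(round(nrow / (1 + (n_strips - 1) * (1 - strip_overlap))))
    strip_h = max(strip_h, 16)
    step = max(int(round(strip_h * (1 - strip_overlap))), 1)
    rows = []
    for i in range(n_strips):
        top = min(i * step, nrow - strip_h)
        bot = top + strip_h
        u, peak = _ncc_axial_shift(reference[top:bot], deformed[top:bot], max_shift)
        rows.append(
            {
                "strip": i,
                # the matched overlap is centered at strip center - u/2 in the
                # reference frame; attaching u there makes the displacement
                # slope exact for affine deformation fields
                "y_center_px": 0.5 * (top + bot) - 0.5 * u,
                "displacement_px": u,
                "correlation": peak,
                "ok": peak >= min_correlation,
            }
        )
    return pd.DataFrame(rows)


def dic_axial_strain(
    reference: np.ndarray,
    deformed: np.ndarray,
    n_strips: int = 10,
    strip_overlap: float = 0.5,
    max_shift: int | None = None,
    min_correlation: float = 0.5,
    n_passes: int = 2,
) -> tuple[float, pd.DataFrame]:
    """Axial (row-direction) compressive strain in percent from a speckle pair.

    Strip-wise normalized cross-correlation gives an axial displacement per
    strip; the strain is the negated least-squares slope of displacement vs
    axial position (compression positive).  A second pass warps the deformed
    image by the first-pass affine estimate and measures the residual, which
    removes the small bias from within-strip stretch.

    Returns (strain_pct, per-strip displacement table of the first pass).
    Raises :class:`DICError` on textureless input; the table attribute
    ``reliable`` is False when more than 25% of strips correlate poorly.
    """
    reference = np.asarray(reference, dtype=float)
    deformed = np.asarray(deformed, dtype=float)
    if reference.shape != deformed.shape:
        raise ValueError("reference and deformed images must have the same shape")
    if reference.std() < 1e-8 or deformed.std() < 1e-8:
        raise DICError("textureless speckle image (variance below threshold)")
    if not 0.0 <= strip_overlap < 1.0:
        raise ValueError("strip_overlap must lie in [0, 1)")
    nrow, ncol = reference.shape
    if max_shift is None:
        max_shift = max(int(0.15 * nrow), 5)

    current = deformed
    scale_total, shift_total = 1.0, 0.0
    first_table: pd.DataFrame | None = None
    for p in range(max(n_passes, 1)):
        table = _strip_displacements(
            reference, current, n_strips, strip_overlap, max_shift, min_correlation
        )
        if first_table is None:
            first_table = table
        good = table[table["ok"]]
        if len(good) < 2:
            raise DICError("fewer than 2 strips with a usable correlation peak")
        slope, intercept = np.polyfit(good["y_center_px"], good["displacement_px"], 1)
        # displacement field u(y) = intercept + slope*y maps ref y -> y + u(y)
        scale_total *= 1.0 + slope
        shift_total = shift_total * (1.0 + slope) + intercept
        if p < n_passes - 1:
            # undo the estimated affine map so the next pass sees the residual
            yy, xx = np.mgrid[0:nrow, 0:ncol].astype(float)
            current = map_coordinates(
                deformed, [scale_total * yy + shift_total, xx], order=1, mode="nearest"
            )
            max_shift = max(5, max_shift // 3)

    strain_pct = -(scale_total - 1.0) * 100.0
    assert first_table is not None
    first_table.attrs["reliable"] = bool((~first_table["ok"]).mean() <= 0.25)
    first_table.attrs["strain_pct"] = strain_pct
    return strain_pct, first_table


def stress_from_load(force_n: float | np.ndarray, disc_diameter_mm: float) -> float | np.ndarray:
    """Axial stress in MPa assuming a circular cross-section: F / (pi d^2 / 4)."""
    if disc_diameter_mm <= 0:
        raise ValueError("disc diameter must be positive")
    area_mm2 = np.pi * disc_diameter_mm**2 / 4.0
    return force_n / area_mm2  # N / mm^2 = MPa


def synchronize_frames(
    load: LoadTrace,
    exposure_start_times: np.ndarray,
    disc_diameter_mm: float,
    exposure_time_s: float = 0.5,
    applied_strain_pct: np.ndarray | None = None,
) -> list[FrameMechanics]:
    """Interpolate the load trace to the midpoint of each exposure window.

    ``applied_strain_pct`` (e.g. from DIC) is carried through when given,
    otherwise strain is left NaN.  Exposures outside the trace span raise.
    """
    t_mid = np.asarray(exposure_start_times, dtype=float) + 0.5 * exposure_time_s
    if t_mid.min() < load.time_s[0] - 1e-9 or t_mid.max() > load.time_s[-1] + 1e-9:
        raise ValueError("exposure window falls outside the load-trace time span")
    force = np.interp(t_mid, load.time_s, load.force_n)
    disp = np.interp(t_mid, load.time_s, load.displacement_mm)
    out = []
    for k in range(t_mid.size):
        eps = float("nan") if applied_strain_pct is None else float(applied_strain_pct[k])
        out.append(
            FrameMechanics(
                frame_index=k,
                applied_strain_pct=eps,
                stress_mpa=float(stress_from_load(force[k], disc_diameter_mm)),
                force_n=float(force[k]),
                displacement_mm=float(disp[k]),
            )
        )
    return out
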