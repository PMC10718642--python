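"""Per-frame and per-series analysis orchestration.

The per-frame recipe mirrors the two-pass structure of beamline practice:

1. a coarse azimuthally averaged radial profile locates the collagen peak and
   its width (EMG fit), fixing the q-band for all azimuthal work;
2. the azimuthal arc profile (matched-filter amplitudes in that band) is
   fitted with two wrapped Gaussians, giving the interlamellar angle and the
   degree of alignment;
3. 10-degree sectors re-centered on the fitted arc azimuths are radially
   integrated and EMG-fitted; the two arcs' peak positions are averaged into
   one d-period (per-arc values are kept for QC) and the FWHM into one
   dispersion value.

Frames whose fits fail are flagged and excluded downstream, never
interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .azimuthal import (
    ArcFitError,
    degree_of_alignment,
    fit_arcs,
    interlamellar_angle,
    matched_azimuthal_profile,
)
from .emg import emg_shape
from .geometry import DetectorImage
from .radial import PeakFitError, d_period, fit_emg_peak, radial_profile, sector_profile

__all__ = ["AnalysisConfig", "analyze_frame", "analyze_series"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis constants (all surfaced in the run configuration).

    q_search bounds the coarse peak hunt; the azimuthal q-band spans
    ``band_fwhm_mult`` fitted FWHM either side of the peak (the band tracks
    the moving peak frame by frame); sectors span ``sector_fwhm_mult`` FWHM.
    """

    q_search: tuple[float, float] = (0.05, 0.15)
    n_q_search: int = 200
    n_phi: int = 180
    band_fwhm_mult: float = 2.0
    sector_width_deg: float = 10.0
    sector_fwhm_mult: float = 4.0
    n_q_sector: int = 80
    tracked_order: int = 1
    alignment_n_phi: int = 180


def analyze_frame(
    image: DetectorImage, config: AnalysisConfig | None = None
) -> dict:
    """Run the full nanoscale analysis on one exposure.

    Returns a flat record with q_peak/angle/alignment/FWHM plus per-arc
    columns and a ``qc_flag`` ('' when clean, otherwise the failure reason);
    failed quantities are NaN.
    """
    cfg = config or AnalysisConfig()
    rec: dict = {
        "q_peak_invnm": np.nan,
        "d_period_nm": np.nan,
        "fwhm_invnm": np.nan,
        "angle_deg": np.nan,
        "center1_deg": np.nan,
        "center2_deg": np.nan,
        "alignment": np.nan,
        "q_peak_arc1": np.nan,
        "q_peak_arc2": np.nan,
        "fwhm_arc1": np.nan,
        "fwhm_arc2": np.nan,
        "fit_residual": np.nan,
        "qc_flag": "",
    }

    # pass 1: coarse peak location from the full-azimuth radial profile
    try:
        coarse = fit_emg_peak(radial_profile(image, cfg.q_search, cfg.n_q_search))
    except (PeakFitError, ValueError) as exc:
        rec["qc_flag"] = f"coarse_peak: {exc}"
        return rec
    q0, fw0 = coarse.q_peak, coarse.fwhm_q
    band = (q0 - cfg.band_fwhm_mult * fw0, q0 + cfg.band_fwhm_mult * fw0)
    shape = lambda q: emg_shape(q, coarse.emg_mu, coarse.emg_sigma, coarse.emg_tau)

    # pass 2: azimuthal arcs
    try:
        prof = matched_azimuthal_profile(image, shape, band, cfg.n_phi)
        arcs = fit_arcs(prof)
        rec["angle_deg"] = interlamellar_angle(arcs)
        rec["center1_deg"] = arcs.center_1
        rec["center2_deg"] = arcs.center_2
        rec["fit_residual"] = arcs.goodness
        if cfg.alignment_n_phi == cfg.n_phi:
            rec["alignment"] = degree_of_alignment(prof)
        else:
            rec["alignment"] = degree_of_alignment(
                matched_azimuthal_profile(image, shape, band, cfg.alignment_n_phi)
            )
    except (ArcFitError, ValueError) as exc:
        rec["qc_flag"] = f"arc_fit: {exc}"
        return rec

    # pass 3: per-arc sector EMG fits, re-centered on the fitted azimuths
    q_lo = max(q0 - cfg.sector_fwhm_mult * fw0, cfg.q_search[0])
    q_hi = min(q0 + cfg.sector_fwhm_mult * fw0, cfg.q_search[1])
    q_peaks, fwhms = [], []
    for i, center in enumerate((arcs.center_1, arcs.center_2), start=1):
        try:
            sec = sector_profile(
                image, center, cfg.sector_width_deg, (q_lo, q_hi), cfg.n_q_sector
            )
            pk = fit_emg_peak(sec)
            rec[f"q_peak_arc{i}"] = pk.q_peak
            rec[f"fwhm_arc{i}"] = pk.fwhm_q
            q_peaks.append(pk.q_peak)
            fwhms.append(pk.fwhm_q)
        except (PeakFitError, ValueError) as exc:
            rec["qc_flag"] = f"sector{i}: {exc}"
    if q_peaks:
        rec["q_peak_invnm"] = float(np.mean(q_peaks))
        rec["d_period_nm"] = d_period(rec["q_peak_invnm"], cfg.tracked_order)
        rec["fwhm_invnm"] = float(np.mean(fwhms))
    return rec


def analyze_series(
    images: list[DetectorImage],
    applied_strain_pct: np.ndarray | None = None,
    config: AnalysisConfig | None = None,
    specimen_id: str = "",
    group: str = "",
) -> pd.DataFrame:
    """Analyze an exposure series and derive frame-0-referenced outcomes.

    Fibril strain is 100 (d - d0)/d0 against the same specimen's first clean
    frame (which must be frame 0: if the unloaded frame fails QC the whole
    series is flagged); fwhm_ratio is normalized to the frame-0 FWHM.
    """
    cfg = config or AnalysisConfig()
    rows = []
    for k, img in enumerate(images):
        rec = analyze_frame(img, cfg)
        rec["frame"] = k
        rec["specimen_id"] = specimen_id
        rec["group"] = group
        rec["applied_strain_pct"] = (
            float(applied_strain_pct[k]) if applied_strain_pct is not None else np.nan
        )
        rows.append(rec)
    df = pd.DataFrame(rows)

    d0 = df.loc[df["frame"] == 0, "d_period_nm"]
    fw0 = df.loc[df["frame"] == 0, "fwhm_invnm"]
    if len(d0) and np.isfinite(d0.iloc[0]):
        df["fibril_strain_pct"] = 100.0 * (df["d_period_nm"] - d0.iloc[0]) / d0.iloc[0]
    else:
        df["fibril_strain_pct"] = np.nan
        df.loc[df["qc_flag"] == "", "qc_flag"] = "no_frame0_reference"
    if len(fw0) and np.isfinite(fw0.iloc[0]) and fw0.iloc[0] > 0:
        df["fwhm_ratio"] = df["fwhm_invnm"] / fw0.iloc[0]
    else:
        df["fwhm_ratio"] = np.nan

    front = [
        "specimen_id",
        "group",
        "frame",
        "applied_strain_pct",
        "angle_deg",
        "fibril_strain_pct",
        "fwhm_invnm",
        "fwhm_ratio",
        "alignment",
        "d_period_nm",
        "q_peak_invnm",
    ]
    rest = [c for c in df.columns if c not in front]
    return df[front + rest]
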