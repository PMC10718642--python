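"""Detector geometry, image I/O, and the pixel -> (q, azimuth) mapping.

Conventions
-----------
* Image origin is the top-left pixel, arrays are row-major; the beam center is
  stored in (x=column, y=row) order and both orderings are spelled out in the
  JSON sidecar schema.
* Azimuth phi is measured in degrees counterclockwise from the detector +x
  axis.  Scattering patterns from fibrous tissue are centrosymmetric (Friedel
  symmetry), so azimuths are folded into [0, 180) everywhere downstream; the
  loading axis sits at phi = 90 deg.
* Negative pixel values mark detector gaps (photon-counting detector
  convention) and are excluded from every profile.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "HC_KEV_NM",
    "DetectorGeometry",
    "DetectorImage",
    "default_geometry",
    "pixel_to_q_phi",
    "q_phi_maps",
    "cake_bins",
    "read_image",
    "write_image",
]

#: h*c in keV*nm; wavelength(nm) = HC_KEV_NM / energy(keV).
HC_KEV_NM = 1.239842

#: Sentinel azimuth reported for the beam-center pixel, where phi is undefined.
PHI_UNDEFINED = float("nan")

_SIDE_CAR_FIELDS = (
    "beam_center_x_px",
    "beam_center_y_px",
    "pixel_size_mm",
    "distance_mm",
    "energy_keV",
)


@dataclass(frozen=True)
class DetectorGeometry:
    """Beam geometry needed to map detector pixels to scattering coordinates.

    Parameters
    ----------
    beam_center:
        (x, y) = (column, row) position of the direct beam, in pixels.
    pixel_size_mm:
        Square pixel edge length in mm.
    distance_mm:
        Sample-detector distance in mm.
    energy_kev:
        Photon energy in keV (10 keV beam by default).
    image_shape:
        (rows, cols) of the detector image.
    """

    beam_center: tuple[float, float]
    pixel_size_mm: float
    distance_mm: float
    energy_kev: float = 10.0
    image_shape: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.pixel_size_mm <= 0 or self.distance_mm <= 0 or self.energy_kev <= 0:
            raise ValueError("pixel size, distance and energy must be positive")
        nrow, ncol = self.image_shape
        if nrow < 1 or ncol < 1:
            raise ValueError("image_shape must be at least 1x1")
        cx, cy = self.beam_center
        # allow the center slightly off-detector but not wildly so
        if not (-ncol <= cx <= 2 * ncol and -nrow <= cy <= 2 * nrow):
            raise ValueError("beam center is far outside the detector")

    @property
    def wavelength_nm(self) -> float:
        return HC_KEV_NM / self.energy_kev

    def q_of_radius_mm(self, r_mm: float | np.ndarray) -> float | np.ndarray:
        """Exact q (nm^-1) at radial distance r_mm from the beam center."""
        two_theta = np.arctan2(r_mm, self.distance_mm)
        return (4.0 * np.pi / self.wavelength_nm) * np.sin(two_theta / 2.0)

    def radius_mm_of_q(self, q: float | np.ndarray) -> float | np.ndarray:
        """Inverse of :meth:`q_of_radius_mm`."""
        theta = np.arcsin(np.asarray(q) * self.wavelength_nm / (4.0 * np.pi))
        return self.distance_mm * np.tan(2.0 * theta)

    def to_sidecar_dict(self) -> dict:
        return {
            "beam_center_x_px": self.beam_center[0],
            "beam_center_y_px": self.beam_center[1],
            "pixel_size_mm": self.pixel_size_mm,
            "distance_mm": self.distance_mm,
            "energy_keV": self.energy_kev,
            "image_shape_rows_cols": list(self.image_shape),
            "axis_convention": "x=column, y=row, origin top-left; phi ccw from +x, folded to [0,180)",
        }

    @classmethod
    def from_sidecar_dict(cls, d: dict) -> "DetectorGeometry":
        missing = [k for k in _SIDE_CAR_FIELDS if k not in d]
        if missing:
            raise ValueError(f"geometry sidecar missing required field(s): {missing}")
        shape = tuple(d.get("image_shape_rows_cols", (256, 256)))
        return cls(
            beam_center=(float(d["beam_center_x_px"]), float(d["beam_center_y_px"])),
            pixel_size_mm=float(d["pixel_size_mm"]),
            distance_mm=float(d["distance_mm"]),
            energy_kev=float(d["energy_keV"]),
            image_shape=(int(shape[0]), int(shape[1])),
        )


@dataclass
class DetectorImage:
    """A single detector exposure: raw counts plus its geometry.

    ``counts`` may contain negative values only as detector-gap markers.
    """

    counts: np.ndarray
    geometry: DetectorGeometry
    frame_index: int = 0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.shape != tuple(self.geometry.image_shape):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match geometry "
                f"image_shape {self.geometry.image_shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True for valid (non-gap) pixels."""
        return self.counts >= 0


def default_geometry() -> DetectorGeometry:
    """Package default geometry.

    The experiment's sample-detector distance is not part of the public record,
    so these values are declared assumptions: 0.172 mm pixels, 6 m camera
    length, 10 keV, 256x256 frame with the beam centered.  They place the
    first-order collagen reflection (q ~ 0.094 nm^-1) at ~65 px radius, well
    inside the detector with room for the background flanks.
    """
    return DetectorGeometry(
        beam_center=(127.5, 127.5),
        pixel_size_mm=0.172,
        distance_mm=6000.0,
        energy_kev=10.0,
        image_shape=(256, 256),
    )


def pixel_to_q_phi(
    geometry: DetectorGeometry, pixel: tuple[float, float]
) -> tuple[float, float]:
    """Map one pixel (x=col, y=row) to (q in nm^-1, phi in degrees, folded).

    Uses the exact q = (4 pi / lambda) sin(theta) with
    2 theta = arctan(r * pixel / distance).  At the beam center q = 0 and phi
    is reported as NaN (undefined).
    """
    x, y = pixel
    cx, cy = geometry.beam_center
    dx = (x - cx) * geometry.pixel_size_mm
    # +y on screen points down; negate so phi is ccw in the usual orientation
    dy = -(y - cy) * geometry.pixel_size_mm
    r = math.hypot(dx, dy)
    q = float(geometry.q_of_radius_mm(r))
    if r == 0.0:
        return 0.0, PHI_UNDEFINED
    phi = math.degrees(math.atan2(dy, dx)) % 360.0
    return q, phi % 180.0


@lru_cache(maxsize=8)
def q_phi_maps(geometry: DetectorGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel q (nm^-1) and folded azimuth (degrees in [0, 180)) arrays.

    Cached per geometry; both the simulator and the analysis modules share it.
    """
    nrow, ncol = geometry.image_shape
    cx, cy = geometry.beam_center
    xs = (np.arange(ncol) - cx) * geometry.pixel_size_mm
    ys = -(np.arange(nrow) - cy) * geometry.pixel_size_mm
    dx, dy = np.meshgrid(xs, ys)
    r = np.hypot(dx, dy)
    q = np.asarray(geometry.q_of_radius_mm(r))
    phi = np.degrees(np.arctan2(dy, dx)) % 180.0
    phi[r == 0] = PHI_UNDEFINED
    return q, phi


def cake_bins(
    geometry: DetectorGeometry,
    q_range: tuple[float, float],
    n_q: int,
    phi_range: tuple[float, float] = (0.0, 180.0),
    n_phi: int = 1,
    mask: np.ndarray | None = None,
) -> dict:
    """Assign every pixel to one half-open (q, phi) bin.

    Returns a dict with flat integer bin indices (``-1`` for out-of-range or
    masked pixels), the bin edges, and per-bin pixel counts.  The assignment
    is a partition: each valid in-range pixel lands in exactly one bin.
    """
    q_lo, q_hi = q_range
    p_lo, p_hi = phi_range
    if not (q_hi > q_lo and p_hi > p_lo):
        raise ValueError("q_range and phi_range must be nonempty (hi > lo)")
    if n_q < 1 or n_phi < 1:
        raise ValueError("bin counts must be >= 1")

    q, phi = q_phi_maps(geometry)
    q_edges = np.linspace(q_lo, q_hi, n_q + 1)
    phi_edges = np.linspace(p_lo, p_hi, n_phi + 1)

    qi = np.floor((q - q_lo) / (q_hi - q_lo) * n_q).astype(np.int64)
    pi = np.floor((phi - p_lo) / (p_hi - p_lo) * n_phi).astype(np.int64)
    in_range = (qi >= 0) & (qi < n_q) & (pi >= 0) & (pi < n_phi) & np.isfinite(phi)
    if mask is not None:
        in_range &= mask

    flat = np.where(in_range, qi * n_phi + pi, -1)
    counts = np.bincount(flat[flat >= 0], minlength=n_q * n_phi)
    if counts.sum() == 0:
        raise ValueError("cake_bins: no pixels fall inside the requested ranges")
    return {
        "bin_index": flat,
        "q_edges": q_edges,
        "phi_edges": phi_edges,
        "n_q": n_q,
        "n_phi": n_phi,
        "pixels_per_bin": counts.reshape(n_q, n_phi),
        "n_out_of_range": int((~in_range).sum()),
    }


def write_image(path: str | Path, image: DetectorImage) -> Path:
    """Write a detector frame as 32-bit float TIFF plus a JSON geometry sidecar.

    The sidecar lives next to the TIFF as ``<stem>.geom.json`` and records the
    axis convention explicitly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.counts.astype(np.float32))
    sidecar = image.geometry.to_sidecar_dict()
    sidecar["frame_index"] = image.frame_index
    sidecar["time_s"] = image.time_s
    path.with_suffix(".geom.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_image(path: str | Path, geometry: DetectorGeometry | None = None) -> DetectorImage:
    """Read a TIFF frame; geometry comes from the sidecar unless given."""
    path = Path(path)
    counts = tifffile.imread(path).astype(np.float64)
    frame_index, time_s = 0, 0.0
    if geometry is None:
        sc_path = path.with_suffix(".geom.json")
        if not sc_path.exists():
            raise FileNotFoundError(
                f"no geometry sidecar {sc_path.name} next to {path.name} and no "
                "geometry passed explicitly"
            )
        sc = json.loads(sc_path.read_text())
        geometry = DetectorGeometry.from_sidecar_dict(sc)
        frame_index = int(sc.get("frame_index", 0))
        time_s = float(sc.get("time_s", 0.0))
    if counts.shape != tuple(geometry.image_shape):
        geometry = replace(geometry, image_shape=counts.shape)
    return DetectorImage(counts=counts, geometry=geometry, frame_index=frame_index, time_s=time_s)
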