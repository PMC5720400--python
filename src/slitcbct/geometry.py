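"""Cone-beam acquisition geometry and the multi-slit collimator (MSC).

The MSC is a fore-collimator of alternating open and closed lead septa laid
out at equal angular intervals on a source-centred arc in the central
sagittal plane.  Because the septa are angular, each one projects onto a
band of constant ``v`` (the detector axis parallel to the rotation axis),
and the projected bands widen slightly toward the detector edge.  A full
acquisition uses two gantry rotations: phase A with the collimator in its
reference position and phase B with the collimator rotated by one septum
interval, so that the open bands of the two phases tile the detector.

Slit widths are expressed at the isocenter plane: a slit of width ``w``
subtends a half-angle ``beta = atan(w / 2 / SAD)`` at the source, so the
radius of the physical collimator track never enters the math.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .errors import InvalidSpecError

__all__ = [
    "ConeBeamGeometry",
    "MSCSpec",
    "DetectorMask",
    "detector_coords",
    "septa_boundaries",
    "open_bands",
    "build_mask",
]


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Circular-orbit cone-beam layout with a flat-panel detector.

    Distances are millimetres.  ``sad`` is the source-to-rotation-axis
    distance, ``sdd`` the source-to-detector distance; their ratio sets the
    projection magnification.  The detector ``u`` axis lies in the rotation
    plane, ``v`` is parallel to the rotation (+z) axis.
    """

    sad: float = 1000.0
    sdd: float = 1500.0
    det_size_u: float = 300.0
    det_size_v: float = 300.0
    n_u: int = 128
    n_v: int = 128
    n_views: int = 360
    arc: float = 360.0

    def __post_init__(self) -> None:
        if not self.sad > 0:
            raise InvalidSpecError(f"sad must be positive, got {self.sad}")
        if not self.sdd > self.sad:
            raise InvalidSpecError(f"sdd ({self.sdd}) must exceed sad ({self.sad})")
        if self.n_u < 1 or self.n_v < 1:
            raise InvalidSpecError("detector must have at least one pixel per axis")
        if self.det_size_u <= 0 or self.det_size_v <= 0:
            raise InvalidSpecError("detector physical size must be positive")
        if self.n_views < 1:
            raise InvalidSpecError("n_views must be at least 1")

    @property
    def pitch_u(self) -> float:
        return self.det_size_u / self.n_u

    @property
    def pitch_v(self) -> float:
        return self.det_size_v / self.n_v

    @property
    def magnification(self) -> float:
        return self.sdd / self.sad

    def angles_deg(self) -> np.ndarray:
        """Uniform gantry angles k * arc / n_views, k = 0 .. n_views-1."""
        return np.arange(self.n_views) * (self.arc / self.n_views)


@dataclass(frozen=True)
class MSCSpec:
    """Multi-slit collimator specification.

    ``slit_width_iso`` is the open-septum width measured at the isocenter
    plane (mm).  ``pitch_ratio`` is the closed/open width ratio; with the
    default 1 the two phases are exactly complementary.  Septa are treated
    as perfect absorbers (10 mm of lead at 40 keV leaks a negligible
    fraction); ``septum_thickness`` is informational.  ``soft_edge_sigma``
    (mm at the detector plane) replaces the ideal step edge with a Gaussian
    ramp of that scale; 0 means ideal edges.
    """

    slit_width_iso: float
    pitch_ratio: float = 1.0
    septum_thickness: float = 10.0
    soft_edge_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not self.slit_width_iso > 0:
            raise InvalidSpecError(
                f"slit_width_iso must be positive, got {self.slit_width_iso}"
            )
        if not self.pitch_ratio > 0:
            raise InvalidSpecError(f"pitch_ratio must be positive, got {self.pitch_ratio}")
        if self.soft_edge_sigma < 0:
            raise InvalidSpecError("soft_edge_sigma must be non-negative")

    def beta_for(self, geometry: ConeBeamGeometry) -> float:
        """Open-septum angular half-width at the source (radians)."""
        return math.atan(0.5 * self.slit_width_iso / geometry.sad)


@dataclass
class DetectorMask:
    """Per-pixel transmission of one MSC phase projected onto the detector.

    ``values`` has shape (n_v, n_u); bands depend only on ``v`` so the mask
    is constant along ``u``.  ``open_bands`` / ``closed_bands`` are
    half-open ``[lo, hi)`` intervals in detector millimetres, clipped to the
    panel and sorted by ``lo``.
    """

    values: np.ndarray
    open_bands: list[tuple[float, float]]
    closed_bands: list[tuple[float, float]]
    phase: str = "A"

    @property
    def open_fraction(self) -> float:
        return float(self.values.mean())


def detector_coords(geometry: ConeBeamGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates (u, v) in mm, centred on the panel midpoint.

    Returns 1D arrays of length ``n_u`` and ``n_v``; pixel (i, j) has its
    centre at ``(-det_size/2 + (i + 0.5) * pitch)`` along each axis.
    """
    u = -0.5 * geometry.det_size_u + (np.arange(geometry.n_u) + 0.5) * geometry.pitch_u
    v = -0.5 * geometry.det_size_v + (np.arange(geometry.n_v) + 0.5) * geometry.pitch_v
    return u, v


def septa_boundaries(
    msc: MSCSpec, geometry: ConeBeamGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered septum edge angles and their detector v-positions.

    With the default ``pitch_ratio`` of 1 the edges sit at odd multiples of
    ``beta = atan(w/2/SAD)``; phase A has an open septum centred on the
    central ray and phase B is the same edge set with open/closed roles
    swapped.  An edge at angle ``theta`` lands on the detector at
    ``v = SDD * tan(theta)``.  Enough edges are emitted to cover the panel.
    """
    beta = msc.beta_for(geometry)
    theta_max = math.atan(0.5 * geometry.det_size_v / geometry.sdd)
    period = 2.0 * beta * (1.0 + msc.pitch_ratio)
    n_half = int(math.ceil((theta_max + period) / period)) + 1
    edges: list[float] = []
    for j in range(-n_half, n_half + 1):
        c = j * period
        edges.append(c - beta)          # open-band lower edge
        edges.append(c + beta)          # open-band upper edge
    theta = np.array(sorted(set(edges)))
    v = geometry.sdd * np.tan(theta)
    keep = np.abs(v) <= 0.5 * geometry.det_size_v + geometry.sdd * math.tan(period)
    return theta[keep], v[keep]


def open_bands(
    msc: MSCSpec, geometry: ConeBeamGeometry, phase: str
) -> list[tuple[float, float]]:
    """Open-septum detector intervals [lo, hi) in mm for one phase, unclipped."""
    if phase not in ("A", "B"):
        raise InvalidSpecError(f"phase must be 'A' or 'B', got {phase!r}")
    beta = msc.beta_for(geometry)
    period = 2.0 * beta * (1.0 + msc.pitch_ratio)
    offset = 0.0 if phase == "A" else 0.5 * period
    theta_max = math.atan(0.5 * geometry.det_size_v / geometry.sdd)
    n_half = int(math.ceil((theta_max + period) / period)) + 1
    bands = []
    for j in range(-n_half, n_half + 1):
        c = j * period + offset
        lo = geometry.sdd * math.tan(c - beta)
        hi = geometry.sdd * math.tan(c + beta)
        if hi < -0.5 * geometry.det_size_v - 1e-9 or lo > 0.5 * geometry.det_size_v + 1e-9:
            continue
        bands.append((lo, hi))
    return sorted(bands)


def _clip_bands(
    bands: list[tuple[float, float]], half: float
) -> list[tuple[float, float]]:
    out = []
    for lo, hi in bands:
        lo_c, hi_c = max(lo, -half), min(hi, half)
        if hi_c > lo_c:
            out.append((lo_c, hi_c))
    return out


def _complement_bands(
    bands: list[tuple[float, float]], half: float
) -> list[tuple[float, float]]:
    out = []
    prev = -half
    for lo, hi in bands:
        if lo > prev:
            out.append((prev, lo))
        prev = max(prev, hi)
    if prev < half:
        out.append((prev, half))
    return out


def build_mask(msc: MSCSpec, geometry: ConeBeamGeometry, phase: str) -> DetectorMask:
    """Rasterize one MSC phase into a per-pixel detector transmission mask.

    Ideal edges classify each pixel centre by its band index, so with
    ``pitch_ratio = 1`` phases A and B partition the detector exactly
    (mask(A) + mask(B) = 1 at every pixel).  With ``soft_edge_sigma > 0``
    the step is replaced by a Gaussian-convolved indicator of the open
    bands, which still sums to 1 across complementary phases.
    """
    if phase not in ("A", "B"):
        raise InvalidSpecError(f"phase must be 'A' or 'B', got {phase!r}")
    _, v = detector_coords(geometry)
    beta = msc.beta_for(geometry)
    theta = np.arctan(v / geometry.sdd)

    if msc.soft_edge_sigma > 0:
        bands = open_bands(msc, geometry, phase)
        sig = msc.soft_edge_sigma
        col = np.zeros_like(v)
        for lo, hi in bands:
            col += ndtr((v - lo) / sig) - ndtr((v - hi) / sig)
        col = np.clip(col, 0.0, 1.0)
    elif msc.pitch_ratio == 1.0:
        # band index m covers theta in [(2m-1) beta, (2m+1) beta); a single
        # floor per pixel guarantees an exact A/B partition
        m = np.floor((theta + beta) / (2.0 * beta)).astype(int)
        want = 0 if phase == "A" else 1
        col = (np.mod(m, 2) == want).astype(float)
    else:
        period = 2.0 * beta * (1.0 + msc.pitch_ratio)
        offset = 0.0 if phase == "A" else 0.5 * period
        loc = np.mod(theta - offset + beta, period)
        col = (loc < 2.0 * beta).astype(float)

    values = np.broadcast_to(col[:, None], (geometry.n_v, geometry.n_u)).copy()
    half = 0.5 * geometry.det_size_v
    ob = _clip_bands(open_bands(msc, geometry, phase), half)
    cb = _complement_bands(ob, half)
    return DetectorMask(values=values, open_bands=ob, closed_bands=cb, phase=phase)
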