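"""Forward model: ray-traced primary projections plus a parametric scatter field.

Primaries follow the monoenergetic Beer-Lambert law along exact analytic
ray-cylinder chords.  Scatter is modelled as a smooth field derived from the
detected fluence: a normalized 2D Gaussian blur of the (masked) primary plus
a flat pedestal, scaled so that the scatter-to-primary ratio in the centre
of the unmasked anterior-posterior view matches a target SPR.  Crucially,
during a collimated acquisition the scatter is generated from the *masked*
fluence: narrowing the beam physically reduces the scatter the object
produces, which is the basis of slit collimation.

Coordinate conventions: the gantry rotates about +z; at angle 0 (the AP
view) the source sits at (0, -SAD, 0) and the beam travels along +y.  The
detector ``u`` axis is the rotated +x axis, ``v`` is +z.  Projection pixel
arrays are shaped (n_v, n_u).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.signal import fftconvolve

from .errors import CalibrationError, ConfigurationError
from .geometry import ConeBeamGeometry, DetectorMask, MSCSpec, build_mask, detector_coords
from .phantoms import Phantom, mu_at

__all__ = [
    "Plane",
    "Projection",
    "ProjectionStack",
    "ScatterParams",
    "AcquisitionPair",
    "line_integral",
    "project_primary",
    "simulate_scatter",
    "calibrate_scatter_scale",
    "acquire",
    "source_position",
    "detector_pixel_positions",
]


class Plane(str, Enum):
    LINE_INTEGRAL = "line_integral"
    PRIMARY = "primary_intensity"
    SCATTER = "scatter_intensity"
    TOTAL = "total_intensity"


@dataclass
class Projection:
    """One detector image at one gantry angle."""

    angle: float
    plane: Plane
    pixels: np.ndarray  # (n_v, n_u), non-negative
    i0: float = 1.0
    line_integrals: np.ndarray | None = None  # populated for primary projections


@dataclass
class ProjectionStack:
    """Per-view detector images sharing one plane and lattice."""

    angles: np.ndarray          # (n,) degrees
    pixels: np.ndarray          # (n, n_v, n_u)
    plane: Plane
    i0: float = 1.0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.pixels.shape[0] != self.angles.shape[0]:
            raise ConfigurationError("stack angle count does not match pixel planes")

    def view(self, k: int) -> Projection:
        return Projection(float(self.angles[k]), self.plane, self.pixels[k], self.i0)


@dataclass(frozen=True)
class ScatterParams:
    """Parametric scatter model.

    ``spr`` is the target scatter-to-primary ratio at the centre of the
    unmasked AP view; ``kernel_sigma`` the Gaussian blur scale in mm at the
    detector plane; ``pedestal_fraction`` the portion of scatter carried by
    a flat offset proportional to the mean detected fluence.
    """

    spr: float = 0.5
    kernel_sigma: float = 30.0
    pedestal_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.spr < 0:
            raise ConfigurationError("spr must be non-negative")
        if self.kernel_sigma <= 0:
            raise ConfigurationError("kernel_sigma must be positive")
        if not 0.0 <= self.pedestal_fraction <= 1.0:
            raise ConfigurationError("pedestal_fraction must lie in [0, 1]")


@dataclass
class AcquisitionPair:
    """The two masked total-intensity stacks plus optional reference and truth."""

    stack_a: ProjectionStack
    stack_b: ProjectionStack
    mask_a: DetectorMask
    mask_b: DetectorMask
    geometry: ConeBeamGeometry
    msc: MSCSpec
    reference: ProjectionStack | None = None      # unmasked primary + scatter
    truth_primary: ProjectionStack | None = None  # unmasked primary only
    truth_scatter_a: ProjectionStack | None = None
    truth_scatter_b: ProjectionStack | None = None


# ---------------------------------------------------------------------------
# geometry helpers

def _rot(angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return math.cos(a), math.sin(a)


def source_position(geometry: ConeBeamGeometry, angle_deg: float) -> np.ndarray:
    """Source location at a gantry angle; angle 0 is the AP view."""
    c, s = _rot(angle_deg)
    # R(angle) @ (0, -sad, 0)
    return np.array([geometry.sad * s, -geometry.sad * c, 0.0])


def detector_pixel_positions(geometry: ConeBeamGeometry, angle_deg: float) -> np.ndarray:
    """World positions of all pixel centres, shape (n_v, n_u, 3)."""
    c, s = _rot(angle_deg)
    u, v = detector_coords(geometry)
    center = np.array([-(geometry.sdd - geometry.sad) * s,
                       (geometry.sdd - geometry.sad) * c, 0.0])
    e_u = np.array([c, s, 0.0])
    e_v = np.array([0.0, 0.0, 1.0])
    return (center[None, None, :]
            + u[None, :, None] * e_u[None, None, :]
            + v[:, None, None] * e_v[None, None, :])


# ---------------------------------------------------------------------------
# primary projector

def _chord_breakpoints(phantom: Phantom, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Parametric breakpoints t in [0, 1] of every element interface crossed.

    ``dst`` has shape (N, 3); returns (N, 2E + 2) sorted breakpoints
    including the endpoints 0 and 1.  Rays that miss an element contribute
    degenerate (zero-length) entries.
    """
    d = dst - src[None, :]
    n = dst.shape[0]
    cols = [np.zeros(n), np.ones(n)]
    for e in phantom.elements:
        dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
        ox = src[0] - e.center_xy[0]
        oy = src[1] - e.center_xy[1]
        a = dx * dx + dy * dy
        b = 2.0 * (ox * dx + oy * dy)
        c = ox * ox + oy * oy - e.radius * e.radius
        disc = b * b - 4.0 * a * c
        hit = (disc > 0) & (a > 0)
        sq = np.sqrt(np.where(hit, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(hit, (-b - sq) / (2.0 * a), 0.0)
            t2 = np.where(hit, (-b + sq) / (2.0 * a), 0.0)
        # rays parallel to the cylinder axis: inside radially or not at all
        vert = (a == 0) & (c < 0)
        t1 = np.where(vert, -np.inf, t1)
        t2 = np.where(vert, np.inf, t2)
        hit = hit | vert
        # clip to the element's z-range
        z0 = src[2]
        with np.errstate(divide="ignore", invalid="ignore"):
            tz1 = np.where(dz != 0, (e.z_lo - z0) / dz, -np.inf)
            tz2 = np.where(dz != 0, (e.z_hi - z0) / dz, np.inf)
        tz_lo = np.minimum(tz1, tz2)
        tz_hi = np.maximum(tz1, tz2)
        # rays parallel to z-planes: inside iff z in range
        par = dz == 0
        in_z = (z0 >= e.z_lo) & (z0 < e.z_hi)
        tz_lo = np.where(par, np.where(in_z, -np.inf, np.inf), tz_lo)
        tz_hi = np.where(par, np.where(in_z, np.inf, -np.inf), tz_hi)
        lo = np.clip(np.maximum(t1, tz_lo), 0.0, 1.0)
        hi = np.clip(np.minimum(t2, tz_hi), 0.0, 1.0)
        empty = ~hit | (hi <= lo)
        cols.append(np.where(empty, 0.0, lo))
        cols.append(np.where(empty, 0.0, hi))
    ts = np.stack(cols, axis=1)
    ts.sort(axis=1)
    return ts


def _line_integrals(phantom: Phantom, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Path integrals of mu (dimensionless) for rays src -> each dst (N, 3)."""
    if not phantom.elements:
        return np.zeros(dst.shape[0])
    ts = _chord_breakpoints(phantom, src, dst)
    d = dst - src[None, :]
    ray_len = np.linalg.norm(d, axis=1)  # mm
    mid = 0.5 * (ts[:, 1:] + ts[:, :-1])         # (N, K)
    seg = ts[:, 1:] - ts[:, :-1]                 # (N, K)
    pts = src[None, None, :] + mid[:, :, None] * d[:, None, :]
    mu = mu_at(phantom, pts.reshape(-1, 3)).reshape(mid.shape)  # 1/cm
    return (mu * seg).sum(axis=1) * ray_len / 10.0


def line_integral(phantom: Phantom, source_point, detector_point) -> float:
    """Exact analytic path integral of mu along one ray (dimensionless).

    Computed from ray-cylinder chord intersections with priority-resolved
    overlaps; mu is in 1/cm and path lengths in mm, so the result is the
    Beer-Lambert exponent.
    """
    src = np.asarray(source_point, dtype=float)
    dst = np.asarray(detector_point, dtype=float)
    if np.allclose(src, dst):
        raise ConfigurationError("source and detector points must be distinct")
    return float(_line_integrals(phantom, src, dst[None, :])[0])


def project_primary(
    phantom: Phantom, geometry: ConeBeamGeometry, angle: float, i0: float = 1.0
) -> Projection:
    """Primary-intensity projection at one gantry angle.

    Per pixel, ``I = i0 * exp(-line integral)`` along the ray from the
    source to the pixel centre; the line-integral plane is retained on the
    returned projection.
    """
    src = source_position(geometry, angle)
    dst = detector_pixel_positions(geometry, angle).reshape(-1, 3)
    p = _line_integrals(phantom, src, dst).reshape(geometry.n_v, geometry.n_u)
    return Projection(angle=angle, plane=Plane.PRIMARY,
                      pixels=i0 * np.exp(-p), i0=i0, line_integrals=p)


# ---------------------------------------------------------------------------
# scatter model

class ScatterSimulator:
    """Precomputed Gaussian kernel and boundary renormalization for one lattice."""

    def __init__(self, geometry: ConeBeamGeometry, params: ScatterParams):
        self.params = params
        su = params.kernel_sigma / geometry.pitch_u
        sv = params.kernel_sigma / geometry.pitch_v
        ru = max(1, int(math.ceil(4.0 * su)))
        rv = max(1, int(math.ceil(4.0 * sv)))
        ku = np.exp(-0.5 * (np.arange(-ru, ru + 1) / su) ** 2)
        kv = np.exp(-0.5 * (np.arange(-rv, rv + 1) / sv) ** 2)
        k = kv[:, None] * ku[None, :]
        self.kernel = k / k.sum()
        ones = np.ones((geometry.n_v, geometry.n_u))
        self._denom = fftconvolve(ones, self.kernel, mode="same")

    def shape(self, fluence: np.ndarray) -> np.ndarray:
        """Unit-scale scatter shape: renormalized blur plus flat pedestal."""
        f = self.params.pedestal_fraction
        blur = fftconvolve(fluence, self.kernel, mode="same") / self._denom
        return (1.0 - f) * np.clip(blur, 0.0, None) + f * fluence.mean()


def simulate_scatter(
    primary: Projection | np.ndarray,
    params: ScatterParams,
    calibration: float,
    geometry: ConeBeamGeometry | None = None,
    simulator: ScatterSimulator | None = None,
) -> Projection:
    """Scatter-intensity plane generated from a (possibly masked) fluence.

    ``scatter = calibration * [(1 - pedestal) * G_sigma * fluence
    + pedestal * mean(fluence)]`` with a renormalized-truncation Gaussian at
    the detector plane.  Feeding the masked fluence makes slit collimation
    reduce total scatter, not merely sample it.
    """
    if isinstance(primary, Projection):
        pix, angle, i0 = primary.pixels, primary.angle, primary.i0
    else:
        pix, angle, i0 = np.asarray(primary, dtype=float), 0.0, 1.0
    if simulator is None:
        if geometry is None:
            raise ConfigurationError("simulate_scatter needs a geometry or a simulator")
        simulator = ScatterSimulator(geometry, params)
    return Projection(angle=angle, plane=Plane.SCATTER,
                      pixels=calibration * simulator.shape(pix), i0=i0)


def calibrate_scatter_scale(
    phantom: Phantom,
    geometry: ConeBeamGeometry,
    params: ScatterParams,
    i0: float = 1.0,
    patch: int = 16,
) -> float:
    """Scale factor mapping the unit scatter shape to the target SPR.

    Chosen so the mean scatter / mean primary over the central
    ``patch x patch`` pixels of the unmasked angle-0 view equals
    ``params.spr``.
    """
    if params.spr == 0:
        return 0.0
    prim = project_primary(phantom, geometry, 0.0, i0=i0)
    sim = ScatterSimulator(geometry, params)
    shape = sim.shape(prim.pixels)
    cv, cu = geometry.n_v // 2, geometry.n_u // 2
    h = patch // 2
    sl = (slice(cv - h, cv + h), slice(cu - h, cu + h))
    p_mean = prim.pixels[sl].mean()
    s_mean = shape[sl].mean()
    if p_mean <= 0 or s_mean <= 0:
        raise CalibrationError("zero primary or scatter in the calibration patch")
    return params.spr * p_mean / s_mean


# ---------------------------------------------------------------------------
# acquisition

def acquire(
    phantom: Phantom,
    geometry: ConeBeamGeometry,
    msc: MSCSpec,
    params: ScatterParams | None = None,
    *,
    angles: np.ndarray | None = None,
    i0: float = 1.0,
    noise_photons: float | None = None,
    seed: int | None = None,
    include_reference: bool = True,
    keep_truth: bool = True,
) -> AcquisitionPair:
    """Simulate the two-rotation slit-masked acquisition.

    For each gantry angle and each collimator phase the detected total is
    ``mask * primary + scatter(mask * primary)``; the optional reference is
    the unmasked ``primary + scatter(primary)``.  With ``noise_photons``
    set, Poisson counting noise is applied at that fluence per unit
    intensity (seeded, reproducible); the default is noiseless so
    algorithmic error is not confounded with counting error.
    """
    if angles is None:
        angles = geometry.angles_deg()
    angles = np.asarray(angles, dtype=float)
    mask_a = build_mask(msc, geometry, "A")
    mask_b = build_mask(msc, geometry, "B")

    sim = scale = None
    if params is not None and params.spr > 0:
        sim = ScatterSimulator(geometry, params)
        scale = calibrate_scatter_scale(phantom, geometry, params, i0=i0)

    n = len(angles)
    shp = (n, geometry.n_v, geometry.n_u)
    tot_a = np.zeros(shp)
    tot_b = np.zeros(shp)
    ref = np.zeros(shp) if include_reference else None
    tprim = np.zeros(shp) if keep_truth else None
    tsc_a = np.zeros(shp) if keep_truth else None
    tsc_b = np.zeros(shp) if keep_truth else None

    rng = np.random.default_rng(seed) if noise_photons else None

    for k, ang in enumerate(angles):
        prim = project_primary(phantom, geometry, float(ang), i0=i0).pixels
        fl_a = mask_a.values * prim
        fl_b = mask_b.values * prim
        if sim is not None:
            sc_a = scale * sim.shape(fl_a)
            sc_b = scale * sim.shape(fl_b)
            sc_ref = scale * sim.shape(prim) if include_reference else None
        else:
            sc_a = sc_b = np.zeros_like(prim)
            sc_ref = np.zeros_like(prim) if include_reference else None
        tot_a[k] = fl_a + sc_a
        tot_b[k] = fl_b + sc_b
        if include_reference:
            ref[k] = prim + sc_ref
        if keep_truth:
            tprim[k] = prim
            tsc_a[k] = sc_a
            tsc_b[k] = sc_b

    if rng is not None:
        q = noise_photons / i0
        tot_a = rng.poisson(tot_a * q) / q
        tot_b = rng.poisson(tot_b * q) / q
        if include_reference:
            ref = rng.poisson(ref * q) / q

    def _stack(pix):
        return ProjectionStack(angles=angles.copy(), pixels=pix, plane=Plane.TOTAL, i0=i0)

    return AcquisitionPair(
        stack_a=_stack(tot_a),
        stack_b=_stack(tot_b),
        mask_a=mask_a,
        mask_b=mask_b,
        geometry=geometry,
        msc=msc,
        reference=_stack(ref) if include_reference else None,
        truth_primary=ProjectionStack(angles.copy(), tprim, Plane.PRIMARY, i0) if keep_truth else None,
        truth_scatter_a=ProjectionStack(angles.copy(), tsc_a, Plane.SCATTER, i0) if keep_truth else None,
        truth_scatter_b=ProjectionStack(angles.copy(), tsc_b, Plane.SCATTER, i0) if keep_truth else None,
    )
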