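"""FDK filtered backprojection for a circular orbit and flat-panel detector.

Standard Feldkamp-Davis-Kress reconstruction: detector coordinates are
rescaled to the isocenter plane, each view is cosine (distance)
pre-weighted, each detector row is ramp-filtered (discrete Ram-Lak impulse
response, optionally Hamming-apodized, zero-padded to the next power of two
at least twice the row length), and voxels accumulate the filtered data
with bilinear detector interpolation and the FDK ``(SAD/U)^2`` distance
weight.  The scaling is chosen so a consistent line-integral stack of a
uniform cylinder reconstructs to its linear attenuation in 1/cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import Plane, ProjectionStack
from .errors import ConfigurationError, UnsupportedOrbitError
from .geometry import ConeBeamGeometry, detector_coords

__all__ = [
    "ReconGrid",
    "Volume",
    "log_normalize",
    "fdk_reconstruct",
    "central_profile",
]


@dataclass(frozen=True)
class ReconGrid:
    """Reconstruction voxel lattice, centred on the isocenter by default."""

    n_x: int = 128
    n_y: int = 128
    n_z: int = 128
    voxel_size: float = 1.5
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.n_x, self.n_y, self.n_z) < 1:
            raise ConfigurationError("grid counts must be at least 1")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be positive")

    def axis_coords(self, axis: str) -> np.ndarray:
        n = {"x": self.n_x, "y": self.n_y, "z": self.n_z}[axis]
        o = {"x": self.origin[0], "y": self.origin[1], "z": self.origin[2]}[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_size + o


@dataclass
class Volume:
    """Reconstructed linear attenuation (1/cm) on a ReconGrid; array is (z, y, x)."""

    values: np.ndarray
    grid: ReconGrid

    def __post_init__(self) -> None:
        expect = (self.grid.n_z, self.grid.n_y, self.grid.n_x)
        if self.values.shape != expect:
            raise ConfigurationError(
                f"volume shape {self.values.shape} does not match grid {expect}"
            )


def log_normalize(stack: ProjectionStack, i0: float | None = None,
                  floor: float = 1e-12) -> ProjectionStack:
    """Convert intensities to line integrals: ``p = -ln(max(I, floor)/i0)``.

    ``floor`` (absolute, same units as the intensities) keeps fully blocked
    pixels finite.  Stacks already in line-integral form pass through.
    """
    if stack.plane == Plane.LINE_INTEGRAL:
        return stack
    if i0 is None:
        i0 = stack.i0
    if not i0 > 0:
        raise ConfigurationError(f"i0 must be positive, got {i0}")
    if not floor > 0:
        raise ConfigurationError("floor must be positive")
    p = -np.log(np.maximum(stack.pixels, floor) / i0)
    return ProjectionStack(angles=stack.angles.copy(), pixels=p,
                           plane=Plane.LINE_INTEGRAL, i0=i0)


def _ramp_filter_freq(pad: int, tau: float, apodization: str | None) -> np.ndarray:
    """rFFT of the discrete Ram-Lak impulse response on a length-`pad` row."""
    n = np.arange(pad)
    k = np.minimum(n, pad - n)  # circular |n|
    h = np.zeros(pad)
    h[0] = 1.0 / (4.0 * tau * tau)
    odd = k % 2 == 1
    h[odd] = -1.0 / (np.pi * k[odd] * tau) ** 2
    H = np.real(np.fft.rfft(h))
    if apodization is None:
        return H
    if apodization == "hamming":
        m = H.size
        window = 0.54 + 0.46 * np.cos(np.pi * np.arange(m) / (m - 1))
        return H * window
    raise ConfigurationError(f"unknown apodization {apodization!r}")


def fdk_reconstruct(
    stack: ProjectionStack,
    geometry: ConeBeamGeometry,
    grid: ReconGrid,
    filter_name: str = "ram-lak",
    apodization: str | None = None,
) -> Volume:
    """Reconstruct a volume from a full-orbit line-integral stack.

    Requires uniformly spaced views covering 360 degrees.  ``filter_name``
    currently selects the Ram-Lak ramp; ``apodization="hamming"`` smooths
    its response.  Output attenuation is in 1/cm.
    """
    if filter_name not in ("ram-lak", "ramlak", "ramp"):
        raise ConfigurationError(f"unknown filter {filter_name!r}")
    if stack.plane != Plane.LINE_INTEGRAL:
        raise ConfigurationError("fdk_reconstruct expects a line-integral stack")
    angles = np.asarray(stack.angles, dtype=float)
    n_views = angles.size
    if n_views < 2:
        raise UnsupportedOrbitError("need at least 2 views")
    d = np.diff(angles)
    if not np.allclose(d, d[0], atol=1e-9):
        raise UnsupportedOrbitError("views must be uniformly spaced")
    if not np.isclose(n_views * d[0], 360.0, atol=1e-6):
        raise UnsupportedOrbitError("orbit must cover a full 360 degrees")

    sad, sdd = geometry.sad, geometry.sdd
    u, v = detector_coords(geometry)
    scale = sad / sdd
    u_i, v_i = u * scale, v * scale           # detector rescaled to isocenter
    tau_u = geometry.pitch_u * scale
    tau_v = geometry.pitch_v * scale

    # cosine (distance) pre-weight
    W = sad / np.sqrt(sad**2 + u_i[None, :] ** 2 + v_i[:, None] ** 2)

    pad = 1 << int(np.ceil(np.log2(2 * geometry.n_u)))
    H = _ramp_filter_freq(pad, tau_u, apodization)

    xs = grid.axis_coords("x")
    ys = grid.axis_coords("y")
    zs = grid.axis_coords("z")
    X, Y = np.meshgrid(xs, ys, indexing="xy")   # (n_y, n_x)
    Xf, Yf = X.ravel(), Y.ravel()
    n_xy = Xf.size
    n_z = zs.size

    vol = np.zeros((n_z, n_xy))
    dbeta = np.deg2rad(d[0])
    u0, v0 = u_i[0], v_i[0]
    n_u, n_v = geometry.n_u, geometry.n_v

    for k in range(n_views):
        a = np.deg2rad(angles[k])
        c, s = np.cos(a), np.sin(a)
        Pw = stack.pixels[k] * W
        Q = np.fft.irfft(np.fft.rfft(Pw, pad, axis=1) * H[None, :], pad, axis=1)
        Q = Q[:, :n_u] * tau_u

        xr = Xf * c + Yf * s            # along e_u
        yr = -Xf * s + Yf * c           # along beam axis from isocenter
        ell = yr + sad                  # distance from source along the axis
        w2 = (sad / ell) ** 2
        uu = xr * sad / ell             # iso-plane detector coordinate
        fu = (uu - u0) / tau_u
        iu = np.floor(fu).astype(np.int64)
        au = fu - iu
        ok_u = (iu >= 0) & (iu < n_u - 1)
        iu_c = np.clip(iu, 0, n_u - 2)

        for j in range(n_z):
            vv = zs[j] * sad / ell
            fv = (vv - v0) / tau_v
            iv = np.floor(fv).astype(np.int64)
            av = fv - iv
            ok = ok_u & (iv >= 0) & (iv < n_v - 1)
            iv_c = np.clip(iv, 0, n_v - 2)
            q00 = Q[iv_c, iu_c]
            q01 = Q[iv_c, iu_c + 1]
            q10 = Q[iv_c + 1, iu_c]
            q11 = Q[iv_c + 1, iu_c + 1]
            val = (q00 * (1 - au) * (1 - av) + q01 * au * (1 - av)
                   + q10 * (1 - au) * av + q11 * au * av)
            vol[j] += np.where(ok, w2 * val, 0.0)

    # half-weight for the doubly-measured full orbit; mm^-1 -> cm^-1
    vol *= 0.5 * dbeta * 10.0
    return Volume(values=vol.reshape(n_z, ys.size, xs.size), grid=grid)


def central_profile(volume: Volume, axis: str, slice_index: int | None = None) -> np.ndarray:
    """Centre-line profile of one slice of the volume.

    ``axis="x"`` (or ``"y"``) profiles the given z-slice through the in-plane
    centre; ``axis="z"`` runs along the rotation axis through the volume
    centre.  ``slice_index`` defaults to the central slice.
    """
    n_z, n_y, n_x = volume.values.shape
    if axis == "x":
        iz = n_z // 2 if slice_index is None else slice_index
        if not 0 <= iz < n_z:
            raise IndexError(f"slice index {iz} out of range [0, {n_z})")
        return volume.values[iz, n_y // 2, :].copy()
    if axis == "y":
        iz = n_z // 2 if slice_index is None else slice_index
        if not 0 <= iz < n_z:
            raise IndexError(f"slice index {iz} out of range [0, {n_z})")
        return volume.values[iz, :, n_x // 2].copy()
    if axis == "z":
        return volume.values[:, n_y // 2, n_x // 2].copy()
    raise ValueError(f"axis must be 'x', 'y' or 'z', got {axis!r}")
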