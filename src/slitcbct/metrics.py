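"""Image-quality metrics: contrast ratio, improvement factor, error profiles.

The contrast ratio of an insert against its surround is
``CR = |I_P - I_W| / I_P`` with ``I_P`` the mean over the surrounding
(body) region and ``I_W`` the mean over the insert region; the improvement
factor is the corrected-image CR divided by the uncorrected-image CR.
Relative-error profiles compare corrected projections against the retained
primary-only truth, and detector-energy profiles integrate the detected
signal per detector row to show that the two-phase slit acquisition
deposits about the same total energy as a conventional open exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import RegionError, UndefinedContrastError

__all__ = [
    "RegionSpec",
    "ContrastReport",
    "contrast_ratio",
    "cr_improvement",
    "relative_error_profile",
    "detector_energy_profile",
]


@dataclass(frozen=True)
class RegionSpec:
    """A rectangular or disk region in physical (mm) image coordinates.

    ``rect``: params = (cx, cy, width, height); ``disk``: params =
    (cx, cy, radius).  Coordinates refer to whichever lattice the region is
    rasterized on (detector u/v for projections, grid x/y for slices).
    """

    shape: str
    params: tuple[float, ...]
    label: str = ""

    def rasterize(self, x_coords: np.ndarray, y_coords: np.ndarray) -> np.ndarray:
        """Boolean membership mask of shape (len(y_coords), len(x_coords))."""
        X, Y = np.meshgrid(x_coords, y_coords)
        if self.shape == "rect":
            cx, cy, w, h = self.params
            m = (np.abs(X - cx) <= w / 2.0) & (np.abs(Y - cy) <= h / 2.0)
        elif self.shape == "disk":
            cx, cy, r = self.params
            m = (X - cx) ** 2 + (Y - cy) ** 2 <= r * r
        else:
            raise RegionError(f"unknown region shape {self.shape!r}")
        if not m.any():
            raise RegionError(f"region {self.label or self.shape} is empty after rasterization")
        return m


@dataclass(frozen=True)
class ContrastReport:
    """Region means and the resulting contrast ratio for one image."""

    i_p: float
    i_w: float
    cr: float
    context: str = ""


def contrast_ratio(
    image: np.ndarray,
    region_p: RegionSpec,
    region_w: RegionSpec,
    x_coords: np.ndarray,
    y_coords: np.ndarray,
    context: str = "",
) -> ContrastReport:
    """Contrast ratio ``|I_P - I_W| / I_P`` between two image regions."""
    m_p = region_p.rasterize(x_coords, y_coords)
    m_w = region_w.rasterize(x_coords, y_coords)
    i_p = float(image[m_p].mean())
    i_w = float(image[m_w].mean())
    if i_p == 0:
        raise UndefinedContrastError("surround region mean is zero; CR undefined")
    return ContrastReport(i_p=i_p, i_w=i_w, cr=abs(i_p - i_w) / i_p, context=context)


def cr_improvement(cr_corrected: float, cr_uncorrected: float) -> float:
    """Ratio of corrected to uncorrected contrast ratio."""
    if cr_uncorrected == 0:
        raise UndefinedContrastError("uncorrected CR is zero; improvement factor undefined")
    return cr_corrected / cr_uncorrected


def relative_error_profile(
    test_profile: np.ndarray,
    reference_profile: np.ndarray,
    reference_floor: float = 0.0,
) -> dict:
    """Percent error of a profile against a reference, sample by sample.

    Samples where the reference is at or below ``reference_floor`` (and
    always where it is zero) are excluded and reported as NaN.  Returns a
    dict with the per-sample ``errors`` (%), ``max_abs``, and the counts of
    compared and excluded samples.
    """
    t = np.asarray(test_profile, dtype=float)
    r = np.asarray(reference_profile, dtype=float)
    if t.shape != r.shape:
        raise ValueError(f"profile lengths differ: {t.shape} vs {r.shape}")
    valid = r > max(reference_floor, 0.0)
    if not valid.any():
        raise ValueError("reference profile has no usable (positive) samples")
    err = np.full_like(r, np.nan)
    err[valid] = 100.0 * (t[valid] - r[valid]) / r[valid]
    return {
        "errors": err,
        "max_abs": float(np.nanmax(np.abs(err))),
        "n_compared": int(valid.sum()),
        "n_excluded": int((~valid).sum()),
    }


def detector_energy_profile(stacks: dict[str, np.ndarray], view: int = 0) -> dict[str, np.ndarray]:
    """Row-integrated detected intensity along v for one view of each stack.

    ``stacks`` maps labels (e.g. phase A, phase B, their raw sum, the
    open-field reference) to pixel arrays shaped (n_views, n_v, n_u) or
    (n_v, n_u); all must share one lattice.  Returns label -> per-row sums.
    """
    shapes = set()
    out = {}
    for label, pix in stacks.items():
        img = pix[view] if pix.ndim == 3 else pix
        shapes.add(img.shape)
        out[label] = img.sum(axis=1)
    if len(shapes) != 1:
        raise ValueError(f"stacks do not share one detector lattice: {shapes}")
    return out
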