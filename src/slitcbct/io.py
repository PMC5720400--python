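"""MetaImage and TIFF I/O for projection stacks, volumes and masks.

Projection stacks are stored as 3D MetaImage files with axes (u, v, angle)
and metadata keys for the plane, incident fluence and angle sampling;
volumes carry their voxel size.  Masks and single views can be exported as
TIFF for quick inspection.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .acquisition import Plane, ProjectionStack
from .errors import ConfigurationError
from .fdk import ReconGrid, Volume
from .geometry import DetectorMask

__all__ = [
    "write_stack",
    "read_stack",
    "write_volume",
    "read_volume",
    "write_mask_tiff",
    "write_view_tiff",
]


def write_stack(path: str | Path, stack: ProjectionStack, extra_meta: dict | None = None) -> None:
    """Write a projection stack as MetaImage (.mhd/.mha); array order (angle, v, u)."""
    img = sitk.GetImageFromArray(stack.pixels.astype(np.float64))
    img.SetMetaData("plane", stack.plane.value)
    img.SetMetaData("i0", repr(float(stack.i0)))
    img.SetMetaData("angles_deg", ",".join(repr(float(a)) for a in stack.angles))
    for k, v in (extra_meta or {}).items():
        img.SetMetaData(str(k), str(v))
    sitk.WriteImage(img, str(path))


def read_stack(path: str | Path) -> ProjectionStack:
    img = sitk.ReadImage(str(path))
    pixels = sitk.GetArrayFromImage(img).astype(float)
    if pixels.ndim != 3:
        raise ConfigurationError(f"{path}: expected a 3D (angle, v, u) stack")
    keys = img.GetMetaDataKeys()
    plane = Plane(img.GetMetaData("plane")) if "plane" in keys else Plane.TOTAL
    i0 = float(img.GetMetaData("i0")) if "i0" in keys else 1.0
    if "angles_deg" in keys:
        angles = np.array([float(x) for x in img.GetMetaData("angles_deg").split(",")])
    else:
        angles = np.arange(pixels.shape[0]) * (360.0 / pixels.shape[0])
    return ProjectionStack(angles=angles, pixels=pixels, plane=plane, i0=i0)


def write_volume(path: str | Path, volume: Volume) -> None:
    img = sitk.GetImageFromArray(volume.values.astype(np.float64))
    vs = volume.grid.voxel_size
    img.SetSpacing((vs, vs, vs))
    sitk.WriteImage(img, str(path))


def read_volume(path: str | Path) -> Volume:
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).astype(float)
    if values.ndim != 3:
        raise ConfigurationError(f"{path}: expected a 3D volume")
    n_z, n_y, n_x = values.shape
    grid = ReconGrid(n_x=n_x, n_y=n_y, n_z=n_z, voxel_size=float(img.GetSpacing()[0]))
    return Volume(values=values, grid=grid)


def write_mask_tiff(path: str | Path, mask: DetectorMask) -> None:
    """Export a detector mask as an 8-bit TIFF (255 = fully open)."""
    tifffile.imwrite(str(path), np.round(mask.values * 255).astype(np.uint8))


def write_view_tiff(path: str | Path, pixels: np.ndarray) -> None:
    """Export one detector view as 32-bit float TIFF."""
    tifffile.imwrite(str(path), pixels.astype(np.float32))
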