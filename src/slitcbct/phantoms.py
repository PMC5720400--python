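"""Analytic cylindrical phantoms and a 40 keV material table.

Two benchmark objects are provided: a "simple" phantom (a paraffin-wax core
in a PMMA cylinder) and a thorax-like "lung-n-bone" phantom (two
low-density lung-equivalent cylinders and one Teflon bone surrogate inside
a PMMA body).  Attenuation is monoenergetic at 40 keV; linear coefficients
come from NIST-style mass-attenuation values times the material density and
every entry is overridable through the material table.

Geometry conventions: elements are circular cylinders with axes parallel to
the rotation (+z) axis; membership uses the half-open rule ``r < R`` and
``z_lo <= z < z_hi`` so points on interfaces resolve deterministically;
overlaps resolve to the highest-priority element (ties to the later entry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "Material",
    "CylinderElement",
    "Phantom",
    "default_materials",
    "build_simple_phantom",
    "build_lung_bone_phantom",
    "mu_at",
]


@dataclass(frozen=True)
class Material:
    """A material with density (g/cm³) and linear attenuation mu at 40 keV (1/cm)."""

    name: str
    density: float
    mu: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ConfigurationError(f"{self.name}: density must be positive")
        if self.mu < 0:
            raise ConfigurationError(f"{self.name}: mu must be non-negative")


def default_materials() -> dict[str, Material]:
    """Material table at 40 keV.

    Linear coefficients are (mass attenuation at 40 keV) x density:

    ======================  =========  ==============  ==========
    material                rho g/cm³  mu/rho cm²/g    mu 1/cm
    ======================  =========  ==============  ==========
    PMMA                    1.19       0.235           0.280
    paraffin wax            0.93       0.228           0.212
    lung-equiv polyurethane 0.26       0.240           0.062
    Teflon (PTFE)           2.20       0.260           0.572
    ======================  =========  ==============  ==========
    """
    return {
        "pmma": Material("PMMA", 1.19, 0.280),
        "paraffin": Material("paraffin wax", 0.93, 0.212),
        "polyurethane": Material("lung-equivalent polyurethane", 0.26, 0.062),
        "teflon": Material("Teflon", 2.20, 0.572),
    }


@dataclass(frozen=True)
class CylinderElement:
    """Axis-aligned circular cylinder; lengths in mm, higher priority overrides."""

    center_xy: tuple[float, float]
    radius: float
    z_lo: float
    z_hi: float
    material: Material
    priority: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError("cylinder radius must be positive")
        if not self.z_hi > self.z_lo:
            raise ConfigurationError("cylinder must have z_hi > z_lo")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test for points of shape (..., 3) in mm."""
        p = np.asarray(points, dtype=float)
        dx = p[..., 0] - self.center_xy[0]
        dy = p[..., 1] - self.center_xy[1]
        inside_r = dx * dx + dy * dy < self.radius * self.radius
        inside_z = (p[..., 2] >= self.z_lo) & (p[..., 2] < self.z_hi)
        return inside_r & inside_z


@dataclass(frozen=True)
class Phantom:
    """An ordered collection of cylinder elements in an air (mu = 0) background."""

    elements: tuple[CylinderElement, ...]
    name: str = "phantom"

    def __init__(self, elements, name: str = "phantom") -> None:
        object.__setattr__(self, "elements", tuple(elements))
        object.__setattr__(self, "name", name)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "elements": [
                {
                    "center_xy": list(e.center_xy),
                    "radius": e.radius,
                    "z_lo": e.z_lo,
                    "z_hi": e.z_hi,
                    "priority": e.priority,
                    "material": {
                        "name": e.material.name,
                        "density": e.material.density,
                        "mu": e.material.mu,
                    },
                }
                for e in self.elements
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Phantom":
        elems = [
            CylinderElement(
                center_xy=tuple(e["center_xy"]),
                radius=e["radius"],
                z_lo=e["z_lo"],
                z_hi=e["z_hi"],
                material=Material(**e["material"]),
                priority=e.get("priority", 0),
            )
            for e in d["elements"]
        ]
        return cls(elems, name=d.get("name", "phantom"))


def mu_at(phantom: Phantom, points) -> np.ndarray:
    """Linear attenuation (1/cm) at one or many points (..., 3) in mm.

    The highest-priority containing element wins; equal priorities resolve
    to the later element in the list; empty space is 0 (air).
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros(p.shape[:-1], dtype=float)
    # stable sort: ascending priority, later elements overwrite earlier ones
    order = sorted(range(len(phantom.elements)), key=lambda i: phantom.elements[i].priority)
    for i in order:
        e = phantom.elements[i]
        out[e.contains(p)] = e.material.mu
    if np.asarray(points).ndim == 1:
        return out[0]
    return out


def build_simple_phantom(materials: dict[str, Material] | None = None) -> Phantom:
    """Coaxial PMMA (15 cm diameter) and paraffin-wax (5 cm) cylinders, 15 cm long."""
    m = materials or default_materials()
    _require(m, ("pmma", "paraffin"))
    return Phantom(
        [
            CylinderElement((0.0, 0.0), 75.0, -75.0, 75.0, m["pmma"], priority=0),
            CylinderElement((0.0, 0.0), 25.0, -75.0, 75.0, m["paraffin"], priority=1),
        ],
        name="simple",
    )


def build_lung_bone_phantom(
    materials: dict[str, Material] | None = None,
    lung_offset_mm: float = 40.0,
    bone_offset_mm: float = -25.0,
) -> Phantom:
    """Thorax-like phantom: PMMA body, two lung-equivalent inserts, one bone rod.

    PMMA body 15 cm diameter x 20 cm; two polyurethane cylinders 5 cm
    diameter x 9 cm at (+-lung_offset, 0); Teflon rod 2 cm diameter x 20 cm
    at (0, bone_offset).  Insert lateral positions are package defaults (the
    benchmark prints only diameters and lengths) and are configurable.
    """
    m = materials or default_materials()
    _require(m, ("pmma", "polyurethane", "teflon"))
    return Phantom(
        [
            CylinderElement((0.0, 0.0), 75.0, -100.0, 100.0, m["pmma"], priority=0),
            CylinderElement((-lung_offset_mm, 0.0), 25.0, -45.0, 45.0, m["polyurethane"], priority=1),
            CylinderElement((lung_offset_mm, 0.0), 25.0, -45.0, 45.0, m["polyurethane"], priority=1),
            CylinderElement((0.0, bone_offset_mm), 10.0, -100.0, 100.0, m["teflon"], priority=1),
        ],
        name="lungbone",
    )


def _require(materials: dict[str, Material], keys) -> None:
    missing = [k for k in keys if k not in materials]
    if missing:
        raise ConfigurationError(f"material table missing entries: {missing}")


def voxelize(phantom: Phantom, shape: tuple[int, int, int], voxel_size: float,
             origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Sample mu (1/cm) on a centred (n_z, n_y, n_x) voxel grid, for export."""
    n_z, n_y, n_x = shape
    xs = (np.arange(n_x) - (n_x - 1) / 2.0) * voxel_size + origin[0]
    ys = (np.arange(n_y) - (n_y - 1) / 2.0) * voxel_size + origin[1]
    zs = (np.arange(n_z) - (n_z - 1) / 2.0) * voxel_size + origin[2]
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    return mu_at(phantom, pts.reshape(-1, 3)).reshape(shape)
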