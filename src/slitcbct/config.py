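"""YAML/JSON configuration: defaults, loading, and object construction."""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from .acquisition import ScatterParams
from .errors import ConfigurationError
from .fdk import ReconGrid
from .geometry import ConeBeamGeometry, MSCSpec
from .phantoms import (
    Material,
    Phantom,
    build_lung_bone_phantom,
    build_simple_phantom,
    default_materials,
)

__all__ = [
    "default_config",
    "load_config",
    "geometry_from_config",
    "msc_from_config",
    "phantom_from_config",
    "scatter_from_config",
    "grid_from_config",
]


def default_config() -> dict:
    """The benchmark conditions: SAD 100 cm, SDD 150 cm, 30x30 cm² 128x128
    panel, 360 views, slit widths in mm at isocenter, SPR 0.5 scatter."""
    return {
        "geometry": {
            "sad": 1000.0, "sdd": 1500.0,
            "det_size_u": 300.0, "det_size_v": 300.0,
            "n_u": 128, "n_v": 128, "n_views": 360, "arc": 360.0,
        },
        "msc": {
            "slit_width_iso": 10.0, "pitch_ratio": 1.0,
            "septum_thickness": 10.0, "soft_edge_sigma": 0.0,
        },
        "phantom": "simple",
        "materials": {},  # overrides of the default 40 keV table
        "scatter": {"spr": 0.5, "kernel_sigma": 30.0, "pedestal_fraction": 0.3},
        "acquisition": {"i0": 1.0, "noise_photons": None, "seed": 0},
        "correction": {"method": "pchip", "u_smooth_window": 0,
                       "sampling": "pixel", "extrapolation": "slope"},
        "recon": {"n_x": 128, "n_y": 128, "n_z": 128, "voxel_size": 1.5,
                  "filter": "ram-lak", "apodization": None},
        "evaluation": {"peripheral_fraction": 0.75},
    }


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults deep-merged with an optional YAML/JSON file and overrides."""
    cfg = default_config()
    if path is not None:
        text = Path(path).read_text()
        loaded = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if loaded:
            _merge(cfg, loaded)
    if overrides:
        _merge(cfg, overrides)
    return cfg


def _merge(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = copy.deepcopy(v)


def geometry_from_config(cfg: dict) -> ConeBeamGeometry:
    return ConeBeamGeometry(**cfg["geometry"])


def msc_from_config(cfg: dict, slit_width: float | None = None) -> MSCSpec:
    block = dict(cfg["msc"])
    if slit_width is not None:
        block["slit_width_iso"] = slit_width
    return MSCSpec(**block)


def materials_from_config(cfg: dict) -> dict[str, Material]:
    table = default_materials()
    for key, spec in (cfg.get("materials") or {}).items():
        table[key] = Material(spec.get("name", key), spec["density"], spec["mu"])
    return table


def phantom_from_config(cfg: dict, name: str | None = None) -> Phantom:
    spec = name if name is not None else cfg["phantom"]
    materials = materials_from_config(cfg)
    if isinstance(spec, dict):
        return Phantom.from_dict(spec)
    if spec == "simple":
        return build_simple_phantom(materials)
    if spec in ("lungbone", "lung-n-bone", "lung_bone"):
        return build_lung_bone_phantom(materials)
    raise ConfigurationError(f"unknown phantom {spec!r}")


def scatter_from_config(cfg: dict) -> ScatterParams | None:
    block = cfg.get("scatter")
    if block is None:
        return None
    return ScatterParams(**block)


def grid_from_config(cfg: dict) -> ReconGrid:
    block = cfg["recon"]
    return ReconGrid(n_x=block["n_x"], n_y=block["n_y"], n_z=block["n_z"],
                     voxel_size=block["voxel_size"])
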