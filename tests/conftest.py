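"""Shared fixtures: bench geometry, phantoms, and cached heavy simulations."""

import numpy as np
import pytest

import slitcbct as sc


@pytest.fixture(scope="session")
def geom():
    """The benchmark cone-beam layout (SAD 1 m, SDD 1.5 m, 30 cm 128-pixel panel)."""
    return sc.ConeBeamGeometry()


@pytest.fixture(scope="session")
def simple_phantom():
    return sc.build_simple_phantom()


@pytest.fixture(scope="session")
def lungbone_phantom():
    return sc.build_lung_bone_phantom()


@pytest.fixture(scope="session")
def scatter_params():
    return sc.ScatterParams()  # spr 0.5, sigma 30 mm, pedestal 0.3


@pytest.fixture(scope="session")
def ap_bench(geom, simple_phantom, lungbone_phantom, scatter_params):
    """AP-view acquisition + correction for both phantoms and all slit widths.

    Returns {(phantom_name, width): (pair, corrected_stack)} computed once.
    """
    out = {}
    for phantom in (simple_phantom, lungbone_phantom):
        for w in (10.0, 20.0, 30.0):
            pair = sc.acquire(phantom, geom, sc.MSCSpec(w), scatter_params,
                              angles=np.array([0.0]))
            corrected, _ = sc.correct_stack(pair)
            out[(phantom.name, w)] = (pair, corrected)
    return out


@pytest.fixture(scope="session")
def cylinder_recon(geom):
    """Uniform cylinder (r 50 mm, mu 0.2/cm), 360 views, 64^3 grid at 2 mm."""
    mat = sc.Material("uniform", 1.0, 0.2)
    phantom = sc.Phantom(
        [sc.CylinderElement((0.0, 0.0), 50.0, -75.0, 75.0, mat)], name="cylinder"
    )
    angles = geom.angles_deg()
    pix = np.stack(
        [sc.project_primary(phantom, geom, float(a)).line_integrals for a in angles]
    )
    stack = sc.ProjectionStack(angles=angles, pixels=pix, plane=sc.Plane.LINE_INTEGRAL)
    grid = sc.ReconGrid(64, 64, 64, 2.0)
    volume = sc.fdk_reconstruct(stack, geom, grid)
    return {"stack": stack, "grid": grid, "volume": volume, "mu": 0.2}


@pytest.fixture(scope="session")
def recon_study(simple_phantom, scatter_params):
    """180-view w=10 simple-phantom study: corrected / uncorrected / primary volumes."""
    geom = sc.ConeBeamGeometry(n_views=180)
    pair = sc.acquire(simple_phantom, geom, sc.MSCSpec(10.0), scatter_params)
    corrected, _ = sc.correct_stack(pair)
    grid = sc.ReconGrid(64, 64, 64, 2.0)
    vols = {
        label: sc.fdk_reconstruct(sc.log_normalize(stk), geom, grid)
        for label, stk in (
            ("corrected", corrected),
            ("uncorrected", pair.reference),
            ("primary", pair.truth_primary),
        )
    }
    return {"geom": geom, "grid": grid, "volumes": vols, "pair": pair}
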