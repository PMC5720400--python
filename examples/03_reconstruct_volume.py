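"""Reconstruct corrected and uncorrected volumes and show cupping removal.

A 180-view orbit of the simple phantom is acquired with the 10 mm collimator,
corrected, log-normalized and FDK-reconstructed.  The central-line profile of
the uncorrected (primary + scatter) volume is depressed and cupped; the
corrected volume lands back on the primary-only reconstruction and its
plateaus read out the true attenuation coefficients.
"""

import numpy as np

import slitcbct as sc

geom = sc.ConeBeamGeometry(n_views=180)
phantom = sc.build_simple_phantom()
pair = sc.acquire(phantom, geom, sc.MSCSpec(10.0), sc.ScatterParams())
corrected, _ = sc.correct_stack(pair)

grid = sc.ReconGrid(64, 64, 64, voxel_size=2.0)
volumes = {
    label: sc.fdk_reconstruct(sc.log_normalize(stack), geom, grid)
    for label, stack in (("corrected", corrected),
                         ("uncorrected", pair.reference),
                         ("primary-only", pair.truth_primary))
}

xs = grid.axis_coords("x")
mats = sc.default_materials()
print(f"true mu: paraffin {mats['paraffin'].mu} /cm, PMMA {mats['pmma'].mu} /cm\n")
for label, vol in volumes.items():
    prof = sc.central_profile(vol, "x")
    core = prof[np.abs(xs) < 20].mean()
    annulus = prof[(np.abs(xs) > 35) & (np.abs(xs) < 65)].mean()
    print(f"{label:13s}: paraffin plateau {core:.4f} /cm, PMMA plateau {annulus:.4f} /cm")

# The uncorrected plateaus are biased low by scatter; the corrected ones match
# the primary-only reconstruction and the true coefficients to within ~1%.
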