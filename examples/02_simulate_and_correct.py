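"""Simulate a slit-masked AP view and run the scatter correction.

For each phantom and slit width: ray-trace the 40 keV primary, add SPR-0.5
parametric scatter generated from the masked fluence, correct by sampling
the closed-septa signal, interpolating the scatter plane, subtracting and
merging the two phases — then compare the corrected projection's z-axis
central profile against the retained primary-only truth.
"""

import numpy as np

import slitcbct as sc

geom = sc.ConeBeamGeometry()
params = sc.ScatterParams(spr=0.5, kernel_sigma=30.0, pedestal_fraction=0.3)

for phantom in (sc.build_simple_phantom(), sc.build_lung_bone_phantom()):
    print(f"\n{phantom.name} phantom:")
    for width in (10.0, 20.0, 30.0):
        pair = sc.acquire(phantom, geom, sc.MSCSpec(width), params,
                          angles=np.array([0.0]))
        corrected, report = sc.correct_stack(pair)
        cu = geom.n_u // 2
        prim = pair.truth_primary.pixels[0][:, cu]
        res = sc.relative_error_profile(corrected.pixels[0][:, cu], prim,
                                        reference_floor=0.01 * prim.max())
        print(f"  w = {width:4.0f} mm: max |relative error| = "
              f"{res['max_abs']:.3f}% over {res['n_compared']} samples "
              f"(clipped pixels: {report['clip_counts'][0]})")

# Values well under 2% mean the correction recovers the primary signal to
# better than the benchmark tolerance at every profile sample.
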