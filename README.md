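# slitcbct

A synthetic bench for **multi-slit-collimator (MSC) scatter reduction in
cone-beam CT (CBCT)**.

Cone-beam CT irradiates a large volume per projection, so a substantial
fraction of the detected signal is scattered radiation: it lowers contrast
and produces the familiar cupping artifact in reconstructed attenuation
maps. One hardware remedy is a static fore-collimator whose open and closed
lead septa sit at equal angular intervals on a source-centred arc. Each
septum projects onto a band of the flat-panel detector: open bands receive
primary + scatter, closed bands receive *scatter only*. Two gantry rotations
are acquired — the second with the collimator rotated by one septum interval
— so the open bands of the two phases tile the detector. Per view and per
phase, the scatter field is estimated by interpolating/extrapolating the
closed-band signal along the band axis, subtracted from the open bands, and
the two half-corrected phases are summed into one scatter-corrected
projection. Volumes are reconstructed with Feldkamp–Davis–Kress (FDK)
filtered backprojection from a full 360° circular orbit.

The package is aimed at people studying scatter-correction algorithms who
want a fully controlled, reproducible stand-in for Monte-Carlo or physical
experiments: every input is generated internally (analytic cylindrical
phantoms, a ray-traced monoenergetic 40 keV primary projector, and a
parametric smooth scatter model), and the ground-truth primary and scatter
planes are retained for validation.

## Model summary

- **Geometry** — source–axis distance 100 cm, source–detector distance
  150 cm, 30×30 cm² detector with 128×128 pixels (2.34 mm pitch), 360 views
  over 360°. Slit widths are specified at the isocenter plane; a slit of
  width *w* subtends the half-angle β = atan(*w*/2/SAD).
- **Primary** — Beer–Lambert along exact analytic ray–cylinder chords:
  I = I₀·exp(−∫μ dl), with 40 keV linear attenuation coefficients
  (PMMA 0.280 cm⁻¹, paraffin 0.212 cm⁻¹, lung-equivalent polyurethane
  0.062 cm⁻¹, Teflon 0.572 cm⁻¹; all overridable).
- **Scatter** — scale·[(1−f)·G_σ ∗ Φ + f·mean(Φ)] where Φ is the (masked)
  detected fluence, G_σ a normalized 2D Gaussian (σ = 30 mm at the
  detector), f = 0.3 a flat pedestal fraction, and the scale is calibrated
  so the scatter-to-primary ratio (SPR) at the centre of the unmasked AP
  view hits a target (default 0.5). Generating scatter from the *masked*
  fluence is what makes slit collimation physically reduce scatter.
- **Correction** — per detector column: sample the closed-septa pixels,
  interpolate along v (monotone piecewise-cubic by default), extrapolate
  past the outermost band with the boundary slope, subtract in the open
  bands (clipping at zero), merge the two phases.
- **Evaluation** — contrast ratio CR = |I_P − I_W| / I_P between a body
  (PMMA) region and an insert (paraffin) region, the improvement factor
  CR_corrected / CR_uncorrected, percent error profiles against the
  primary-only truth, and row-integrated detector-energy profiles.

## Worked example

```python
import numpy as np
import slitcbct as sc

geom = sc.ConeBeamGeometry()                       # the benchmark layout
params = sc.ScatterParams(spr=0.5, kernel_sigma=30.0, pedestal_fraction=0.3)
phantom = sc.build_simple_phantom()                # PMMA body + paraffin core

pair = sc.acquire(phantom, geom, sc.MSCSpec(slit_width_iso=10.0), params,
                  angles=np.array([0.0]))          # two-phase AP acquisition
corrected, report = sc.correct_stack(pair)

cu = geom.n_u // 2
prim = pair.truth_primary.pixels[0][:, cu]
res = sc.relative_error_profile(corrected.pixels[0][:, cu], prim,
                                reference_floor=0.01 * prim.max())
print(f"max |relative error| = {res['max_abs']:.3f}%")
```

This prints `max |relative error| = 0.255%`: after correction, the central
z-axis profile of the merged projection agrees with the primary-only truth
to 0.255% at every sample — far inside the 2% benchmark tolerance. Running
all six configurations (both phantoms × slit widths 10/20/30 mm, see
`examples/02_simulate_and_correct.py`) gives a worst case of 1.736%
(simple phantom, 30 mm slits).

The reconstruction example (`examples/03_reconstruct_volume.py`) prints

```
corrected    : paraffin plateau 0.2121 /cm, PMMA plateau 0.2800 /cm
uncorrected  : paraffin plateau 0.1936 /cm, PMMA plateau 0.2490 /cm
primary-only : paraffin plateau 0.2121 /cm, PMMA plateau 0.2799 /cm
```

i.e. scatter biases the uncorrected attenuation low (with a cupped profile),
while the corrected volume reads back the true coefficients (0.212 and
0.280 cm⁻¹). The contrast example (`examples/04_contrast_and_energy.py`)
shows the improvement factor growing with SPR (×1.043 / ×1.075 / ×1.119 at
SPR 0.25 / 0.5 / 1.0) and the two slit phases depositing exactly the energy
of one conventional open exposure.

A thin CLI wraps the same pipeline:

```bash
slitcbct simulate --out sim/                # write phase A/B + reference stacks
slitcbct correct --stack-a sim/phase_a.mhd --stack-b sim/phase_b.mhd --out corr.mhd
slitcbct reconstruct --stack corr.mhd --out vol.mhd
slitcbct run --out results/ --slit-width 10 --phantom simple --recon
```

## Layout

- `src/slitcbct/geometry.py` — cone-beam layout, septa, detector masks
- `src/slitcbct/phantoms.py` — materials and analytic cylinder phantoms
- `src/slitcbct/acquisition.py` — ray-traced primaries, scatter model, acquisition
- `src/slitcbct/correction.py` — sample / interpolate / subtract / merge
- `src/slitcbct/fdk.py` — log normalization and FDK reconstruction
- `src/slitcbct/metrics.py`, `experiment.py` — evaluation metrics and orchestration
- `src/slitcbct/io.py`, `config.py`, `cli.py` — MetaImage/TIFF I/O, YAML config, CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
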