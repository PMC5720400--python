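# Methods

This note records the models behind the bench, the parameters that matter,
the numerical choices, and what the synthetic results do and do not say
about real systems.

## The acquisition model

**Geometry.** A circular cone-beam orbit about +z. At gantry angle 0 (the
anterior–posterior view) the source is at (0, −SAD, 0) and the beam travels
along +y; the detector `u` axis is the rotated +x axis and `v` is parallel
to the rotation axis. Defaults: SAD 1000 mm, SDD 1500 mm (magnification
1.5), 30×30 cm² panel with 128×128 pixels (2.34 mm pitch), 360 views.
Angles are k·(360/n_views)°.

**Collimator.** Open and closed septa alternate at equal angular intervals
on a source-centred arc in the central sagittal plane. Widths are defined at
the isocenter plane — a slit of width *w* subtends half-angle
β = atan(*w*/2/SAD) — so the physical track radius never enters the math.
With equal open/closed widths (pitch ratio 1, the default) the septum edges
sit at odd multiples of β and each pixel is classified by a single band
index, which makes the phase A/B masks an exact partition of the panel.
Septa are perfect absorbers: 10 mm of lead transmits a negligible fraction
at 40 keV, so leakage is ignored. An optional `soft_edge_sigma` replaces the
ideal step with a Gaussian-convolved indicator (mm at the detector plane);
complementary soft masks still sum to one and the merge renormalizes by the
summed mask weight.

**Phantoms.** Axis-aligned circular cylinders with priority-resolved
overlaps; membership uses half-open conventions (r < R, z_lo ≤ z < z_hi) so
rays tangent to interfaces resolve deterministically. The *simple* phantom
is a 15 cm PMMA cylinder with a 5 cm paraffin core, 15 cm long. The
*lung-n-bone* phantom is a 20 cm-long, 15 cm PMMA body with two 5 cm
lung-equivalent polyurethane cylinders (9 cm long, at x = ±40 mm) and one
2 cm Teflon rod (full length, at y = −25 mm). The insert lateral positions
are package defaults chosen to mimic a thorax layout; only the diameters
and lengths are prescribed by the benchmark. Densities of 0.26 g/cm³
(lung-equivalent foam) and 2.2 g/cm³ (Teflon) are used; the printed
benchmark values of 0.021/0.025 g/cm³ are physically implausible for those
materials and are treated as typographical. Linear attenuation coefficients
at 40 keV come from standard mass-attenuation tables times density —
PMMA 0.280, paraffin 0.212, polyurethane 0.062, Teflon 0.572 cm⁻¹ — and
every density/μ is overridable through the material table.

**Primary projector.** Monoenergetic Beer–Lambert: per pixel,
I = I₀·exp(−∫μ dl) along the ray from the source to the pixel centre. The
path integral is exact: each cylinder contributes a chord interval from the
ray–cylinder quadratic clipped to its z-range; the sorted interval
breakpoints split the ray into segments whose μ is evaluated at segment
midpoints with priority resolution. The detector is an ideal fluence
integrator (no energy response, glare or lag).

**Scatter model.** Scatter is a smooth parametric field derived from the
detected fluence Φ:

    S = c · [(1 − f) · G_σ ∗ Φ + f · mean(Φ)]

with G_σ a normalized 2D Gaussian at the detector plane (σ = 30 mm default,
boundary-renormalized truncation so a constant fluence maps to itself) and
f = 0.3 a flat pedestal. The scale c is calibrated once per phantom so that
mean(S)/mean(P) over the central 16×16 pixels of the *unmasked* AP view
equals the target SPR (0.5 default). During a collimated acquisition S is
generated from the *masked* fluence with the same c: halving the beam
roughly halves the scatter, which is the physical basis of the method. The
model is linear in the fluence, so the two phase scatter fields sum exactly
to the open-field scatter — the detector-energy comparison between the two
slit phases and a conventional exposure is exact by construction.

SPR 0.5 represents a moderately scattering mid-size object; σ = 30 mm makes
the field smooth on the 10 mm-slit band pitch while still carrying spatial
structure; the pedestal represents the long-range scatter floor a large air
gap produces. Noise is off by default (to separate algorithmic from
counting error); an optional Poisson mode at a stated photons-per-unit
fluence is seeded and reproducible.

## The correction

Behind a closed septum no primary reaches the detector, so the recorded
signal *is* the scatter plane there. Per view and per phase, each detector
column is processed independently in v:

1. **Sample** the closed-septa signal. Default `sampling="pixel"`: every
   closed pixel row is a sample. The alternative `"band"` mode condenses
   each closed band to its band mean placed at the mean v of its member
   rows (noise suppression at the cost of v-resolution). At least two
   closed bands must project onto the panel.
2. **Interpolate** along v through the samples: monotone piecewise-cubic
   (PCHIP, default — no overshoot into negative scatter) or linear. Beyond
   the outermost samples the default `extrapolation="slope"` continues the
   boundary derivative linearly; `"constant"` holds the end value. The
   estimate is clipped at 0. An optional moving-average window along u can
   suppress column noise (off by default).
3. **Subtract** the estimate from the open-band pixels, clipping negatives
   at zero (clip counts are reported as a quality diagnostic); closed-band
   pixels are zeroed since they carry no primary.
4. **Merge** the two phases by pixelwise sum (a partition-of-unity with
   ideal complementary masks; divided by the summed mask weight when edges
   are soft).

**Why pixel sampling and slope extrapolation are the defaults.** The
scatter field of this bench is not flat everywhere: the Gaussian blur of
the bright unattenuated fluence just outside a phantom's shadow creates
ramps on the 30 mm kernel scale, and for 20–30 mm slits the band pitch
(30–45 mm on the detector) exceeds that scale. One band-mean sample per
closed band then aliases the ramp and the residual reaches ~12% of the
local primary at 30 mm slits; keeping every closed pixel recovers the full
information the closed septa actually measure and brings the worst residual
to 1.74%. Likewise, where the outermost band of one phase is open, the
field keeps changing past the last sample; continuing the boundary slope
rather than freezing the end value cuts the edge residual about twofold.
Under strong noise the band-mean / constant-extrapolation combination is
the more robust choice and both remain selectable.

Error behaviour: if the true scatter is constant or linear per column the
corrected view equals the true primary exactly (up to the zero-clip); for
smooth fields the estimate error is second order in the band pitch, which
the suite verifies by pitch-halving (≈4× error reduction).

## Reconstruction

Standard FDK for a flat panel on a full 360° orbit: detector coordinates
rescaled to the isocenter plane, cosine (distance) pre-weighting,
row-wise ramp filtering — discrete Ram–Lak impulse response sampled at the
iso-plane pitch, zero-padded to the next power of two ≥ 2·n_u, optional
Hamming apodization — and voxel-driven backprojection with bilinear
detector interpolation, the (SAD/U)² distance weight, Δβ angular weighting
and the factor ½ for the doubly-measured full orbit. Intensities are
converted to line integrals by p = −ln(max(I, floor)/I₀) with a small
positive floor for fully blocked pixels. Output is linear attenuation in
cm⁻¹; a noiseless uniform cylinder reconstructs its mid-plane μ to ≈0.02%
on a 64³/2 mm grid, and the simple-phantom plateaus read back their input
coefficients to ≈1% — the default grid is 128³ at 1.5 mm, and the test and
acceptance studies use 64³ at 2 mm with 180–360 views to keep runtimes in
seconds. Non-uniform or partial orbits are rejected (no short-scan
weighting; the benchmark uses full orbits only).

## Evaluation

Contrast ratio CR = |I_P − I_W| / I_P, with I_P the mean over the
surrounding (PMMA) region and I_W over the insert region. Default regions:
in projections, 20×20 mm rectangles at the detector centre (insert) and at
45 mm lateral offset at the isocenter scaled by the magnification (body);
in axial slices, the analogous rectangles in volume mm. The "peripheral"
slice sits at 75% of the phantom half-length. All region placements are
configurable; the benchmark figures define them only graphically. The CR
improvement factor is CR_corrected / CR_uncorrected. Because the absolute
scatter magnitude of the original Monte-Carlo study was never published,
absolute improvement factors of this bench are not comparable to the
published ones; the bench instead verifies the properties that do not
depend on that magnitude: scatter strictly degrades CR, the corrected CR
lands within 2% of the primary-only CR, and the improvement factor exceeds
one and grows with SPR.

## Known limitations

- Monoenergetic 40 keV transport with no beam hardening, no bowtie, no
  detector energy response: the bench isolates the *algorithm*, not
  spectral effects.
- The scatter surrogate is generated from the detected fluence; real
  object scatter originates inside the patient and is additionally smeared
  by the air gap. Passing the bench shows the estimator recovers any
  smooth additive field of the stated class, not that a real system meets
  the same numbers.
- Perfect inter-rotation registration is assumed; penumbra, septa leakage
  and patient motion between the two rotations are out of scope (an
  optional soft-edge parameter exists for sensitivity studies only).
- Phantoms are z-aligned cylinders; FDK cone artifacts for strongly
  z-varying objects are therefore mild by construction.
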