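# Methods

## Spot model

A PBS spot measured in air is modelled as a rotationally symmetric mixture
of a Gaussian core and a broader Gaussian halo,

    I(r) = (1 − w) exp(−r² / 2σc²) + w exp(−r² / 2σh²),

with halo weight w ∈ [0, 1), core width σc > 0 and halo width σh > σc; the
peak is 1 by construction. This is the standard double-Gaussian description
of the in-air halo: the core comes from the beam optics, the halo from
large-angle scattering in beam-line components and air, strongest at low
energies.

Per-energy defaults (`default_spot_model`) are obtained by solving the
three closed-form level-crossing equations I(W_f/2) = f for
f = 0.5, 0.1, 0.01 against the published film width triplets
(FWHM, FW10%, FW1%) at each energy and position. At 70–130 MeV the triplets
are exactly representable (residuals ~10⁻¹⁵) and yield w ≈ 0.4–0.5 with
σh/σc ≈ 1.4 — a heavy but only moderately wider second component. At
≥150 MeV the published ratios are *sub-Gaussian* (FW10/FWHM below
√(ln 10 / ln 2) ≈ 1.823), which no core-plus-broader-halo mixture can
produce; there the model degrades to a single Gaussian pinned to the FWHM,
accepting a ~1–3 mm overshoot of the printed FW1% at the highest energies.
The halo-dominated low energies, which drive the small-field effects this
package is about, are matched exactly.

Coordinates are continuous millimetres with the origin at the grid centre,
x along columns, y along rows (increasing with row index), and pixel
centres at (i − n/2 + 0.5)·pitch. Default pixel pitch is 0.5 mm for both
devices (the panel's native resolution; the film scan pitch is a free
choice and is kept equal for comparability).

## Detector model

`render_exposure` maps a truth grid through a parametric detector:

1. **Exposure scaling.** The 1× shot is scaled so its peak sits at the
   device's first-shot level — 6 Gy for film (8 Gy saturation) and
   800 counts for the panel (1000-count ceiling) — leaving headroom so the
   base exposure never clips; magnified shots multiply this by 20 or 400.
   Ideal devices (infinite range, zero noise) apply no scaling and are used
   as oracles.
2. **Directional over-response (panel only).** Pixels with y > 0 are
   boosted by a factor ramping from 1 at ≥10% of the image peak to
   1 + `artifact_max_fraction` (default 0.40) at ≤1% of the peak, linearly
   in log₁₀ of relative intensity. The direction, ceiling and low-dose
   onset reflect the documented behaviour of scintillator-CCD panels; the
   log-linear ramp between the anchors is this package's choice, since only
   those anchors are constrained.
3. **Noise.** Multiplicative Gaussian, value ← value·(1 + fN(0,1)) with
   f = `noise_fraction` (default 0.001), drawn per pixel from a seeded
   generator; each exposure of a set uses an independent child seed, so a
   set is bit-reproducible from its seed.
4. **Clipping.** Values above the saturation level are clamped and flagged;
   flagging is exact (a pixel is flagged iff its pre-clamp value exceeds
   the level).

What the generator does **not** emulate: film-chemistry response curves and
scanning artifacts, CCD optics (glare, blooming), beam-delivery output
drift between exposures, and any in-medium (depth-dependent) halo. Passing
tests therefore demonstrate the correctness of the analysis chain under
the stated statistical model, not the behaviour of any physical detector.

## Pair-magnification compositing

Registration estimates each exposure's (dx, dy) offset against the first by
exhaustive integer-pixel search of the normalized cross-correlation over
mutually trusted pixels (unsaturated and below 0.8× saturation), refined
with a parabolic fit through the correlation peak; synthetic sub-pixel
shifts are recovered to a few micrometres, far inside the 0.1 mm target.

Stitching assigns each pixel to the **highest magnification in which it is
trusted**, divided by that magnification, so every pixel is served by the
exposure with the best signal-to-noise ratio that did not clip. Where a
higher level's raw value lies in the hand-over band between 0.4× and 0.8×
saturation, adjacent levels are cross-faded with weights linear in
intensity; on noiseless input both levels equal the truth, so the blend is
exactly continuous, and the composite equals the stored truth to machine
precision on every valid pixel (a tested invariant). Pixels saturated in
every exposure are flagged invalid rather than raising. Relative
uncertainty is propagated per pixel as the root-sum-square of the blend
weights times the device noise fraction, assuming independent exposures,
and the result is normalized to a peak of 1.

With the default 0.1% per-pixel noise the composite tracks the truth to
about 0.1% (1σ) down to 10⁻⁴ of the peak. The **maximum** per-pixel error
over the ~10⁴ evaluated pixels is necessarily larger — the expected extreme
of that many 0.1% Gaussian deviates is ≈ 0.45% — and the core region is
served by a single exposure, so no stitching rule can average it down;
spatial smoothing is excluded because it would bias the noiseless
composite. The acceptance suite reports this maximum honestly.

## Radial analysis

Profiles are built by converting valid pixels to polar coordinates about
the spot centre (the intensity-weighted centroid of the top-5% region,
sub-pixel) and averaging intensity in 0.5 mm radius bins, restricted to a
polar-angle interval. For panel images the default interval is the quarter
of the circle geometrically opposite the +y over-response — 225–315° in
this package's convention (0° along +x, counter-clockwise) — which is the
same far-from-camera-neck quarter quoted as 135–225° in the published
figures' own angle convention; film uses the full circle. The profile peak
is defined as the mean intensity within r < 1 mm (robust to single-pixel
noise), and widths are read off at the first outward crossing of each
level by linear interpolation between bins — an interpolation, not a fit,
matching how the averaged profiles are described. On pure-Gaussian
synthetics the chain recovers 2σ√(2 ln(1/f)) within one bin for
f = 0.5, 0.1, 0.01.

Device comparison tables report a − b (mm) and (a − b)/b × 100 per energy
with an arithmetic-mean row; the second argument (the panel, by
convention) is the denominator. Printed per-row table values reflect
rounding of unrounded underlying data, so the mean rows are the
reproducible surface.

## Field size factors

`spot_positions` lays out round(L/d) intervals per axis (d = 2.5 mm
spacing), symmetric about the field centre, spots on the field edges, so
the delivered side is that count × d and a centre spot exists for even
interval counts. The central dose is Σ_p kernel(−p), optionally averaged
over a deterministic Cartesian sampling of a 2 mm-radius disc (the
in-plane surrogate for an ion chamber's spherical volume average; the
profiles are 2D in-air images, so a disc is the natural analogue).
FSF(L) = dose(L)/dose(L₀) with L₀ = 100 mm, exactly 1 at L₀.

For a single-Gaussian kernel the continuum limit is
erf(L/(2√2σ))²/erf(L₀/(2√2σ))². Because the (n+1)-spot lattice is the
midpoint quadrature of a uniform field one spacing *wider* than the
delivered side, the oracle is evaluated at L_delivered + d
(`effective_side`); with that pairing the lattice agrees with the closed
form to ≲0.4% for σ ≥ d (dominated by the d²/24 midpoint-rule edge term),
and to ~10⁻⁸ for large σ/d. Grid-backed kernels are zero outside the
measured extent and bilinear between pixels (sub-pixel evaluation error
≤0.1% of peak at the default pitch); a warning is emitted when the largest
field extends beyond the kernel support, since far-tail contributions are
then truncated. The calculator works in-air at the measurement plane and
makes no depth correction.

## Pipeline, formats, reproducibility

The pipeline driver loops (energy, position, device), derives a per-stage
seed from the run seed by hashing the stage labels (SHA-256, reduced below
2³¹), and writes composites (float32 TIFF + 8-bit mask sidecar, geometry
in a JSON image description), radial profiles and tables (CSV, 9
significant digits so printed values round-trip), and a manifest with the
configuration, seed and per-file SHA-256 checksums; two runs with the same
configuration produce identical checksums.

## Problem sizes and defaults

Synthetic grids extend 5 outer sigmas from the spot centre (≈130×130
pixels at 70 MeV); exposure series use factors (1, 20, 400); the
registration search window is ±3 mm. The fidelity summary in the
acceptance script averages 10 seeded repeats. These sizes make every stage
deterministic-fast while keeping all four intensity decades and all
saturation regimes in play.

## Known limitations

- The generator's device model is parametric; it validates the analysis
  chain, not detector physics (see above).
- Sub-Gaussian published width triplets (≥150 MeV) are represented by
  single Gaussians; their FW1% is not matched.
- The over-response ramp shape between its two anchors is a stand-in; only
  direction, ceiling and onset are constrained.
- Absolute dosimetry, depth-dose and range-shifter effects, multi-energy
  plans and treatment-planning-system interaction are out of scope; FSFs
  are relative, in-air, single-layer quantities.
- Reference ion-chamber FSF curves are not available as data, so FSF
  percent-error tables in the pipeline compare the single-Gaussian
  surrogate against the halo-included kernel rather than against a
  measured reference.
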