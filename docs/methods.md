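# Methods

This note documents the models, defaults, and numerical choices behind
`discsaxs`, in the spirit of a beamline-analysis methods section. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scattering model and geometry

The detector pattern is modeled as

I(q, φ) = b₀ + b₁·q⁻ᵖ + A·S(q)·G(φ)

where S(q) is an exponentially modified Gaussian (EMG) — a Gaussian of
center μ and width σ convolved with a one-sided exponential of mean τ toward
larger q — normalized to unit height at its mode, and G(φ) is a pair of
wrapped Gaussian arcs at azimuths 90° ± θ/2 (loading axis vertical at 90°;
Friedel mirrors handled by folding azimuth into [0°, 180°)). θ is the
interlamellar angle. The EMG captures the asymmetry of the meridional
collagen reflection; in the τ→0 limit it reduces exactly to a Gaussian
(mode = μ, FWHM = 2√(2 ln 2)·σ), which the code switches to below
τ/σ = 10⁻⁶ for numerical stability (the general evaluation uses `erfcx`
with an asymptotic branch for the deep tail).

Pixels map to scattering coordinates with the exact expression
q = (4π/λ)·sin(θ_s), 2θ_s = arctan(r·p/L) — the small-angle approximation
would be accurate to ~10⁻⁶ here, but the exact form costs nothing and
removes an approximation from the books. Azimuth is measured
counterclockwise from the detector +x axis with the image origin top-left
and the beam center stored in (x = column, y = row) order; the JSON sidecar
spells this out to preclude the classic transpose bug. Negative counts mark
detector gaps (photon-counting convention) and are excluded everywhere; the
simulator uses this to mask a 12-px beamstop.

### Geometry and pattern defaults (declared assumptions)

The experiment these methods target did not publish its camera length,
detector binning, d-period reference, tracked diffraction order, or photon
budget, so the following are package assumptions, chosen once for
realism and configurability, not measurements:

| parameter | default | rationale |
| --- | --- | --- |
| photon energy | 10 keV | stated beam energy; λ = hc/E = 0.1239842 nm |
| pixel size | 0.172 mm | photon-counting (Pilatus-class) pixel pitch |
| camera length | 6000 mm | places the first-order collagen peak at ~65 px radius on a 256×256 frame |
| image size | 256×256 px | keeps simulation cheap while leaving background flanks around the peak |
| d-period d₀ | 67 nm | canonical collagen axial stagger |
| tracked order n | 1 | fibril strain depends only on the *relative* q shift, so the order is a convention; it cancels in ε_f |
| radial FWHM | 0.005 nm⁻¹ | ~5% of q₀, a sharp but resolvable reflection |
| EMG tail τ | 0.0015 nm⁻¹ | mild asymmetry toward larger q |
| background | 0.05 + 5·10⁻⁵·q⁻³ | smooth power-law small-angle background |
| photons/exposure | 5·10⁶ | bright-synchrotron counting statistics for a 0.5-s exposure |

The loading protocol follows the published numbers: 0.25% applied strain/s,
0.5-s exposures every 3 s, to 10% maximum compression — giving frames at
0, 0.75, 1.5, …, 9.75% plus a final frame at exactly 10% (15 exposures).
Disc geometry defaults: 3.5 mm diameter, 1.4 mm height.

## The forward simulator

`render_pattern` inverts the model per frame: the EMG center is placed so
the *mode* sits at q = 2πn/(d₀(1 + ε_f/100)); σ is solved (Brent) so the
numerically measured FWHM of the rendered EMG equals the frame's target; the
arc width is solved so the degree-of-alignment of the noiseless azimuthal
profile (180 bins) equals the frame's alignment target, raising an explicit
error when the target is outside what two wrapped arcs can produce
(≈ [0.05, 0.99] depending on θ). Poisson noise is applied to the expected
counts with a per-frame seed derived from the specimen seed via
`SeedSequence`, so a fixed specimen seed reproduces the series bitwise.
The noise model is Poisson only — appropriate for photon-counting detectors;
no gain, readout, point-spread, or polarization effects.

### Trajectory presets

Preset trajectories interpolate the published endpoint anchors with
monotone piecewise-cubic curves (PCHIP), since the underlying curves are
smooth and monotone but not available in closed form:

* **lean** — angle 97° → +10° by 3% applied strain → +26° total at 10%;
  fibril strain linear to 2.0% at 10%; FWHM constant; alignment rising
  linearly 0.55 → 0.70.
* **diabetic** — angle 97° → +10° by 3% → +18° total at 10%; fibril strain
  near-linear to ~1.5% at 8% then plateauing at 1.4%; FWHM constant to 4%
  then broadening 25% by 10%; alignment rising to 0.63 at 8% then declining
  to 0.61.

The alignment values and the FWHM broadening magnitude are not published
numbers; they are package choices consistent with the qualitative published
description. Stress presets are explicitly illustrative (no quantitative
stress anchors exist): smooth monotone curves in which the diabetic disc is
stiffer in the toe region and the lean disc stiffer in the linear stage.
They are excluded from quantitative validation.

## Analysis pipeline

Each frame is processed in three passes:

1. **Coarse peak hunt.** The full-azimuth radial profile over
   q ∈ [0.05, 0.15] nm⁻¹ (200 bins) is EMG-fit to locate q₀ and the FWHM,
   fixing the azimuthal q-band at q₀ ± 2·FWHM. The band therefore tracks
   the moving peak frame by frame (a fixed band would drift off the peak at
   2% fibril strain).
2. **Azimuthal arcs.** Arc amplitudes vs azimuth are extracted by per-bin
   matched filtering: each 1° bin gets a two-parameter least-squares fit of
   a·S(q) + c to its pixels, with S the pass-1 radial shape. A plain
   per-bin mean would alias badly — each azimuthal bin holds only ~20
   pixels whose q values sample the sharp radial peak differently,
   imprinting multiplicative jitter that biases the concentration
   statistic upward by several hundredths. A common mis-specification of S
   rescales all bins equally, to which both the arc centers and the
   alignment statistic are invariant. The profile is fit with two wrapped
   Gaussians plus a constant baseline, initialized at the two most
   prominent local maxima separated by ≥ 30° (tie-break: the most-separated
   pair among the top four prominences); fewer than two detectable maxima
   flags the frame. The interlamellar angle is the difference of the fitted
   centers; the alignment statistic is computed on the same matched
   profile.
3. **Sector peak fits.** 10°-wide sectors re-centered on the two fitted arc
   azimuths (the arcs rotate by up to 13° under load) are radially
   integrated over q₀ ± 4·FWHM and fit with EMG + local linear background.
   Each radial bin's abscissa is the *mean pixel q in that bin*, not the
   nominal bin center — pixel q values are not uniform within a bin, and
   bin-center abscissae alias the curved peak into a deterministic position
   error of ~10⁻³ relative q, which (being shared across same-geometry
   specimens) would not average out at cohort scale. The reported peak
   position is the numerically located EMG mode (parameterization-
   independent, and the feature that visibly shifts with strain); FWHM is
   measured numerically from the fitted curve. The two arcs' values are
   averaged into one d-period and FWHM per frame; per-arc values are kept
   as QC columns.

Fibril strain references each specimen's own frame-0 (unloaded) d-period;
a failed frame-0 fit invalidates the series rather than borrowing a
cross-specimen reference. The ±4-FWHM sector window balances background
leverage against the curvature error of the local-linear background model;
±2 starves the background fit and ±6 admits enough power-law curvature to
bias the mode by ~10⁻³ relative.

### Degree of alignment

The statistic is a Gini-style concentration measure: with N bins and
intensity fractions sorted descending, let c_k be the cumulative fractions
and A = mean(c_k); then

alignment = (A − (N+1)/(2N)) / (1 − (N+1)/(2N)).

It equals 1 when one bin holds everything, 0 for a uniform profile, is
invariant to bin permutation and intensity rescaling, and strictly
decreases when intensity moves from a fuller to an emptier bin (property-
tested). The verbal description it concretizes (sorting azimuthal
intensities and measuring how much falls into few bins) admits other
formulas; this one was chosen for satisfying both endpoint conditions with
strict monotonicity under spreading. Background-subtracted (matched-filter)
intensities are the default input; `azimuthal_profile(...,
subtract_background=False)` supports the raw variant.

## Speckle DIC

Applied strain is measured by strip-wise 1D DIC: ~10 half-overlapping
axial strips, each matched to the reference by normalized cross-correlation
of the full 2D strip over integer axial lags (the whole lateral extent
contributes texture, suppressing false matches) with parabolic sub-pixel
refinement. Two corrections matter at the 0.01-point level:

* each displacement is attached to the overlap's center in the *reference*
  frame (strip center − u/2), which makes the displacement slope exact for
  affine deformations;
* a second pass warps the deformed image by the first-pass affine estimate
  and measures the residual, removing the bias from within-strip stretch.

Strain is the negated least-squares slope of displacement vs axial
position, ×100, so compression is positive (matching the applied-
compressive-strain sign convention throughout). Strips with correlation
peaks below 0.5 are dropped; if more than 25% fail the result is flagged
unreliable, and textureless input raises. DIC strain is authoritative for
applied strain; crosshead displacement is retained only as a QC column
since machine compliance is unknowable. Synthetic recovery across seeds
and strains 0–10% is within 0.01 points (tested at 0.1).

## Trajectory statistics

Per-specimen outcomes are interpolated linearly onto a common strain grid
(no extrapolation — grid points outside a specimen's range are masked) and
averaged per group; the contrast is the diabetic-minus-lean difference
curve. Uncertainty comes from a nonparametric bootstrap resampling
specimens with replacement within each group (2000 replicates, percentile
95% band, seeded). This deliberately replaces the original mixed-model
machinery (random intercepts, polynomial strain terms, Kenward–Roger
degrees of freedom): the scientific object — the difference trajectory and
its 95% band — is preserved, while the inference is transparent and
reproducible without a proprietary statistics stack. Consequently the
package does not attempt to reproduce published P-values, and group means
are raw interpolated averages, not model predictions.

Endpoint metrics are evaluated at the 10% reporting strain: total angle
increase, fibril strain, strain-transfer fraction (100·ε_f/ε_app), and
average angular rate (increase/10, °/% strain). Report-table percent
differences are rounded to integers; raw values are returned alongside.

## Validation scales

The test suite uses: single noiseless frames for bias checks (angle within
0.2°, fibril strain within 0.02 points, FWHM within 2%); 50-seed Monte
Carlo runs for the profile-level fitters; 25–50 speckle pairs for DIC; and
one full simulated study (7 lean + 6 diabetic specimens × 15 frames at
default counting statistics) for cohort-scale recovery (group-mean angle
increases within 1°, fibril strains within 0.1 points, and a
diabetic-minus-lean angle difference of ≈ −8° whose 95% band excludes
zero). `scripts/acceptance.py` re-runs the lean cohort end to end in under
a minute.

## What the simulator does and does not emulate

It emulates: the two-arc geometry and its rotation under load, the d-period
shift and dispersion of the collagen reflection, alignment concentration,
Poisson counting noise, the exposure cadence, beamstop masking, and
speckle-image kinematics. It does not emulate: physical form/structure
factors, multiple diffraction orders, crimp sub-populations (more-than-two-
arc azimuthal structure), detector point-spread/gain/readout, sample
absorption or polarization, within-disc heterogeneity of the lamellae, or
viscoelastic load redistribution. Passing the round-trip tests therefore
demonstrates that the estimators are unbiased and precise *under the
parametric model*, not that the model captures every feature of real
patterns — in particular, real azimuthal profiles with crimp-induced
diffuse rings may yield alignment values offset from these presets.

## Other limitations

* Calibration is sidecar-driven; calibrant-ring (e.g. silver behenate)
  refinement, detector tilt, flat-field, and solid-angle corrections are
  out of scope.
* The two sectors are fit separately and averaged; fitting one combined
  profile would weight arcs by amplitude instead.
* Frames failing QC are excluded and logged, never interpolated.
* Bootstrap bands at n = 6–7 specimens per group are approximate; the
  coverage sanity check tolerates the small-sample anticonservatism of the
  percentile method.
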