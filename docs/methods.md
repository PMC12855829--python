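# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `moondvm`. Everything quantitative asserted here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from stored results.

## 1. Sky geometry and surface illuminance

**Ephemerides.** Solar and lunar positions use truncated low-precision
Meeus series (solar: mean longitude/anomaly with the equation of centre;
lunar: the ~27 largest longitude/distance terms and 13 latitude terms of
the main lunar series, with the eccentricity correction on solar-anomaly
terms). The lunar altitude carries a first-order topocentric parallax
correction, −π·cos(alt) with π = asin(R⊕/Δ). Accuracy targets are ±0.5° in
altitude (verified against an independently implemented NOAA-style solar
calculator) and ~1% in illuminated fraction (verified against the
documented disc illumination of the 2022 sampling nights). Valid window
1900–2100; dates outside raise.

**Phase.** The phase angle i follows from the geocentric elongation ψ via
tan i = R sinψ / (Δ − R cosψ); the illuminated fraction is (1 + cos i)/2 by
definition, an invariant enforced at construction.

**Surface illuminance** is a documented simplified model, not a port of any
existing sky package:

* solar term: 118,000·sin(h) + 500 lx for altitude h ≥ 0; for twilight
  (−18° ≤ h < 0) log₁₀E falls linearly from log₁₀(500) at the horizon to
  −3 at h = −18°. This reproduces the qualitative daylight/civil/nautical
  decades; it is deliberately brighter at the civil-twilight end than a
  full radiative model, which matters only for the first half-hour of a
  night series and washes out under covariate standardization (§4).
* lunar term: apparent magnitude m = −12.73 + 0.026·α + 4·10⁻⁹·α⁴ (α =
  phase angle, degrees), converted to illuminance by E = 10^(−0.4(m+14.18))
  lx, dimmed by 10^(−0.4·k·X) with extinction k = 0.25 mag/airmass
  (default, configurable) and the optical-pathlength airmass
  X = 1/(cos Z + 0.025·e^(−11 cos Z)), scaled by the inverse-square
  mean-distance ratio and projected onto the horizontal by sin(alt). A full
  moon at zenith under clear sky yields ≈ 0.21 lx, inside the 0.1–0.4 lx
  literature band.
* starlight baseline 0.001 lx (moonless, sunless sky including airglow);
* cloud factor: a multiplicative transmission per okta (1.00 down to 0.31
  at okta 8, non-increasing by construction). The field campaign excluded
  cloudy nights (mean okta < 1), so default runs use okta 0.

**Underwater attenuation.** A single wavelength-integrated diffuse
attenuation coefficient per profile, E(z) = E₀·e^(−Kd·z), evaluated at the
midpoints of half-open 10 cm bins [z, z+0.1). Default Kd = 0.25 m⁻¹ (clear
hardwater-lake regime); configurable. Values below the floor (default
0.001 lx, the lowest scotopic sensitivity recorded in fish) are reported as
exactly zero. 16.7 m of water gives 167 bins.

**Radiometric conversions** use the CIE 1931 2° photopic table at 5 nm
steps with linear interpolation: E[W m⁻²] = lux/(683·V(λ)) and
photon flux = E·λ/(h·c·N_A). At the blue–green monochromatic approximation
(λ = 500 nm) 0.06 lx ↔ 2.72·10⁻⁴ W m⁻² ↔ 1.14·10⁻³ µmol m⁻² s⁻¹; at
520 nm, 0.001 lx ↔ 2.06·10⁻⁶ W m⁻². At 480 nm the photopic table gives
1.05·10⁻⁵ W m⁻² for 0.001 lx; conversions quoted elsewhere for the blue
end of underwater spectra depend on which luminosity function is assumed
and are not targeted here.

## 2. The synthetic study

The generator's defaults are the study conditions; they are fixed once and
not tuned per test.

**Layout.** Four late-summer dates (2022-08-25, 2022-09-13, 2022-09-29,
2022-10-12; two near new moon, two near full), a 16.7 m water column, one
daylight profile per date (~16:00 CET) plus a half-hourly evening series.
The night-design table holds 54 profiles (13/14/13/14 per date, starting at
the end of civil twilight computed from the ephemeris) × 167 bins × 3 size
classes = 27,054 rows; the day–night table 70 profiles (17/18/17/18) =
35,070 rows. The published field schedule reports a mean of 17.5 profiles
per night, slightly more than the arithmetic of a strict half-hourly series;
profile cadence and counts are therefore configuration, with defaults chosen
to reproduce the analysed row counts exactly.

**Environment.** Temperature is a logistic thermocline (20 °C surface, 8 °C
bottom, centre 6 m, width 1.5 m); chlorophyll-a is a 2 µg/L baseline plus a
Gaussian deep maximum (amplitude 4 µg/L at 8 m); phycoerythrin peaks deeper
(10.5 m), mirroring the deep cyanobacteria layer of stratified hardwater
lakes; oxygen stays above 3 mg/L everywhere. Seeded noise perturbs curve
*parameters*, not values, so the structural invariants (monotone
temperature, peak ordering, oxic column) hold for every seed; a 100-seed
sweep asserts this.

**Densities.** Bin densities are drawn from the night (or day–night) gamma
log-link mixed model with the published coefficient tables as defaults,
random-intercept SDs σ_date = 0.2 and σ_profile = 0.14 (the square roots of
the reported variance components), and gamma shape k = 2 — a realistic
overdispersion for counts-per-bin converted to densities. Light covariates
come from the actual sky model at each profile's time, attenuated and
floored; temperature and chlorophyll come from the date's environment
curves. Illuminance therefore has a realistic mixed distribution (about
half the night bins are floored to zero; moonlit epilimnion bins reach a
few × 10⁻² lx).

**Individuals.** Given bin densities, organism counts are
Poisson(density × 0.52 L), the volume of a fully covered bin
(52 mm breadth × 100 mm path × 100 mm height). Depths are uniform within
the bin, ESDs uniform within the row's size-class range, lateral positions
uniform across the frame breadth. Cladocerans are ovoids (axis ratio
1.2–1.8, no appendages); copepods are elongated (ratio 2.2–3.0) with two
thin antenna strokes. For end-to-end depth-recovery scenarios, a separate
entry point draws depths from a truncated normal whose *truncated* mean and
SD are solved (by root finding on the truncnorm moments) to match a target
daytime distribution; those profiles use the medium and large cladoceran
classes, which remain measurable on downscaled frames, at an expected 600
individuals per profile (≈ 7 ind/L over the 87 L a profile samples —
an ordinary cladoceran density for a productive lake, and enough that the
Monte Carlo error of a 2-profile mean depth stays well inside ±0.5 m).

**Rendering.** Frame k spans [k·Δ, k·Δ + 43 mm] with Δ = (5 m/min)/(2.4
frames/s) = 34.72 mm, i.e. 8.28 mm overlap between consecutive frames. The
background is bright (grey level 200) with a smooth multiplicative
illumination gradient (±10% horizontally, a quarter of that vertically) and
Gaussian sensor noise (SD 2 grey levels). Silhouettes are dark ellipses
(grey 40) whose prolate-spheroid ESD equals the generating ESD exactly:
major = ESD·r^(2/3), minor = ESD·r^(−1/3) for axis ratio r. `scale_factor`
∈ {1, 2, 4, 8} divides the 2048 × 2476 px frame dimensions and multiplies
the 21 µm pitch, for desk-scale runs. Rendering is deterministic given
(seed, config) — byte-identical on repeat runs.

What the generator deliberately does **not** emulate: optical blur and the
depth-of-field resolution loss of a real collimated path, marine
snow/detritus, overlapping or touching organisms beyond chance coincidence,
species-level morphology, nauplii. Passing tests therefore demonstrate the
correctness of the *computation* (segmentation arithmetic, binning,
statistics), not robustness to real-water image degradation — the
classifier interface is pluggable precisely so a learned model can replace
the rule-based stand-in on real imagery.

## 3. Image processing

Flat-fielding divides by a per-pixel median background (estimated over
windows of 21 frames — organisms are sparse, so the median is background),
rescales the ratio to unit mean and maps back to 8-bit at the original mean
level; a 20% illumination gradient is reduced to < 1% background CV, and a
second application changes pixels by < 0.5%.

Segmentation thresholds at background mean − 3σ (shadowgraph particles are
dark on bright) with an Otsu fallback when that is degenerate, and labels
8-connected components. ROI thresholds default to 50–500,000 px at full
resolution (the smallest admissible organism, 0.36 mm ESD ≈ 230 px, clears
the lower bound with margin; divide by scale_factor² when downscaled).

Morphometry fits the moment ellipse to the silhouette **body**, isolated by
a small morphological opening (radius 2 px at full resolution) so that thin
antennae do not inflate the axes; the removed residual supplies the
protrusion count. ESD = (major·minor²)^(1/3) — the prolate-spheroid volume
model, which reduces to the diameter for circular bodies and is standard in
plankton imaging. On rendered silhouettes the 99th-percentile ESD error is
≤ 5% at full resolution; the median error stays ≤ 12% at scale factor 4.
Depth is frame top + centroid row × pitch, accurate to a pixel for whole
silhouettes (organisms clipped at a frame edge are re-imaged whole in the
neighbouring frame thanks to the 8.28 mm overlap).

The default classifier is a transparent rule: copepod if aspect ≥ 2 or ≥ 2
thin protrusions; cladoceran if compact (aspect < 2) and solid
(solidity ≥ 0.9); otherwise "other"; scores are bounded margins in [0, 1].
On noiseless generator silhouettes the two classes are separable by
construction (accuracy ≥ 95% asserted). Any callable
`morphometry -> (taxon, score)` can replace it.

Detections with ESD ≤ 0.36 mm are discarded — below the instrument's
trustworthy practical resolution.

## 4. Assembly and the mixed models

**De-overlap** is keep-first: frame k keeps the part of its span not
covered by frame k−1's kept strip; for spacings ≤ frame height the strips
partition [first top, last bottom] exactly (property-tested), and a
detection outside its own frame's strip is a duplicate and dropped.

**Binning.** Density = count / (breadth × path × kept-strip length in the
bin); a fully covered bin samples 0.52 L. Every taxon × size-class
combination is emitted for covered bins (zeros included); bins with zero
kept coverage emit no row rather than fabricating a zero observation.
Σ density × volume equals the retained detection count exactly, per
profile × taxon × class. ESD size classes are closed intervals per taxon
(cladocerans: 0.36–0.39 / 0.45–0.53 / 0.70–0.75 mm; copepods: 0.36–0.37 /
0.45–0.47 / 0.66–0.68 mm); ESDs in the gaps are "unclassified", excluded
from model rows and tallied in an audit table — the classes are histogram
modes and the space between them belongs to no mode.

**Models.** Both designs are gamma GLMMs with log link and random
intercepts for date and profile. The night design z-scores illuminance,
temperature and chlorophyll (three-way interaction coefficients are only
comparable on a common scale, and the reported night-model coefficient
magnitudes are consistent with standardized covariates); the day–night
design keeps raw lux, whose five-orders-of-magnitude day/night contrast is
the predictor of interest (per-lx slopes are then ~10⁻⁶). The scaling
constants travel with the fit for interpretability.

**Estimation** is Laplace-approximated ML. For candidate (k, σ²_date,
σ²_profile) the joint mode over (β, u) is found by penalized IRLS — under
the log link the expected Fisher weight is the constant k, so the
normal-equation cross-products are computed once per dataset and each
inner step is a single linear solve with step-halving (the joint objective
is monotone). The marginal log-likelihood is the joint log-density at the
mode minus ½·log det(I + k·D·ZᵀZ). The outer search is Nelder–Mead on the
log-parameters; the reported optimizer trace is best-so-far and hence
non-decreasing. With both variances pinned to zero the fit reproduces an
independent gamma GLM (statsmodels IRLS) to < 10⁻⁴ relative — the oracle
contract. Zero-density rows are dropped before fitting by default (gamma
support excludes zero); the alternative half-quantum offset policy and the
count of affected rows are always carried in the fit.

With only 4 date levels σ²_date is weakly identified; it is reported, but
the bootstrap intervals are the authoritative uncertainty statement.

**Inference.** Parametric bootstrap: simulate new random intercepts and
gamma noise from the fitted model, refit, repeat (default 10,000; tests and
desk-scale runs use 50–200), summarize each fixed effect and variance
component by the shortest interval containing 95% of the draws (sorted
draws, sliding window of ⌈0.95·n⌉, width ties broken toward the point
estimate). An effect is significant when its interval excludes zero.
Bootstrap HPD coverage of a true coefficient is ≈ 95% (checked at reduced
iteration counts against binomial tolerance); identical seeds give
identical intervals.

## 5. Validation harnesses and problem sizes

`validation.recover_night_coefficients` simulates densities at the full
study dimensions (27,054 rows) from the published coefficient table of
either taxon and refits; 10 seeds average out simulation noise (each fit
takes well under 2 s thanks to the precomputed cross-products). The
covariate layout uses a fixed study-conditions seed; only density noise
varies. `validation.recover_daytime_mean_depth` renders two daytime
profiles at scale factor 4 (~480 frames of 512 × 619 px each), runs the
full imaging chain, and compares the mean detected cladoceran depth to the
generating truncated normal. These sizes keep the complete suite under two
minutes while leaving the recovery Monte Carlo error far inside the
tolerances being tested.

## 6. Conventions and degenerate inputs

* Depth is positive downward from the surface; bins are half-open
  [z, z+0.1), 0-indexed, reported by midpoint; a frame's recorded depth is
  its top edge and row 0 is its shallowest row.
* Twilight phases assign boundary altitudes to the darker phase
  (−6° is nautical, −18° is night).
* Blank frames segment to zero components; empty vignettes raise;
  single-detection summaries report SE 0; empty detection tables propagate
  as empty outputs, never as errors.
* All randomness flows from one root seed through named substreams
  (SeedSequence spawning), so every pipeline stage is independently
  reproducible and full runs are byte-identical.

## 7. Known limitations

* The sky model is monochromatic-photopic; it ignores spectral shifts with
  lunar elevation, scattering anisotropy, and skyglow, and its twilight
  curve is a one-parameter decade ramp.
* A single Kd per profile; no depth-varying attenuation or inelastic
  scattering.
* The Laplace approximation shares lme4-style profiling of β within the
  penalized solve; for small group counts (4 dates) variance components
  are shrunk relative to REML-style estimates, which is why bootstrap
  intervals, not Wald errors, carry the inference.
* The rule-based classifier is a stand-in calibrated to the generator's
  silhouette geometry; on real imagery it should be replaced through the
  pluggable interface.
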