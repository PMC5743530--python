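# Methods

This note documents the models, conventions and numerical choices behind
`hemiphoto`, and what the synthetic validation does and does not show.

## Projection model

All lenses are treated as azimuthal equidistant: the zenith angle of the
viewed direction is proportional to the pixel distance from the optical
centre, θ = (r / radius_px) · max_zenith. Circular images put the full
hemisphere (max_zenith = 90°) inside an inscribed circle; diagonal
smartphone frames are rectangles whose image diagonal spans the lens FOV,
so a 150° lens puts the frame corners at θ = 75°. Lenses wider than 180°
are handled by calibrating `radius_px` to the 90° ring; the ring beyond the
horizon is excluded by the circular coverage mask. Other projection
families (equisolid, stereographic) are out of scope.

Conventions, fixed to remove ambiguity:

- Continuous pixel centres at (row + 0.5, col + 0.5), raster origin top-left.
- Sky azimuth 0° = North, clockwise (East = 90°). For an upward-looking
  image displayed as captured, image-up is North and East appears on the
  image left; a `mirror` flag serves images flipped before processing.
- `north_offset` rotates image-up onto compass North; for diagonal frames
  the long-axis bearing ("orientation") sets it.
- Directions exactly on a grid-cell edge fall in the lower-index bin.

## Merging a diagonal pair

Two frames taken at the same spot with orientations 90° apart (tolerance
15°, configurable) are merged *geometrically* from their recorded compass
orientations — no feature matching. The merged raster is a full-hemisphere
circle whose diameter in source-pixel units is the frame diagonal × 180/150:
under the equidistant law this inscribes each frame so its diagonal spans
exactly 150°, leaving the 75–90° band and the inter-cardinal corners
unobserved. The E–W frame wins wherever both frames see a direction.
Unobserved disk pixels carry coverage 0 and are counted as *obstructed* in
all downstream statistics (a "renormalise over covered area" alternative
exists but is off by default). For two 3264 × 1836 frames the covered share
of the analysis disk is 0.543 — about half, which is why merged estimates
are only trustworthy when the unobserved regions are mostly canopy anyway
(dense horizons), the situation the zenith-loaded synthetic scenes and most
closed-canopy forests present.

The 180/150 diameter ratio deserves a remark: expressed as a multiplier on
the diagonal it must exceed 1 for the analysis circle to be *larger* than
the merged image, which is the only reading consistent with the equidistant
law; the ratio is exposed as a parameter (`fov_ratio`) for other lens FOVs.

## Segmentation

`isodata_blue` iterates the Ridler–Calvard fixed point
t ← (mean(values ≤ t) + mean(values > t))/2 on the blue channel, starting
at the global mean, stopping when the update moves < 0.5 intensity or after
100 iterations. Sky is `blue > t` (ties to canopy); uncovered pixels are
never sky.

`enhanced` scores each pixel's sky membership from the bi-hexcone
(HSL-family) colour attributes and thresholds the *score field* with the
same IsoData rule. The score is a product (fuzzy AND) of two memberships:

- brightness: trapezoid rising on lightness ∈ [0.10, 0.55];
- colour: hue membership 1.0 on the blue sector (180–300°), 0.1 on
  green/yellow (60–180°), 0.3 elsewhere, *relaxed towards 1 as chroma falls
  below ≈ 0.1* (achromatic pixels — clouds, grey sky — carry no hue
  information and should not be penalised).

The product form was chosen over a weighted sum because it is the only
simple combination that simultaneously (a) sends bright achromatic pixels
to score ≈ 1, (b) scores saturated bright blue > 0.8, and (c) keeps bright
but green/yellow foliage below the threshold — the defining behaviour of
colour-based canopy classifiers. Weights of any additive blend provably
cannot achieve (a) and (b) together once the achromatic hue fallback is
below 1. No parity with any particular third-party classifier is claimed;
the method is validated behaviourally (identical to the blue-channel method
on clean two-tone images; strictly fewer sunlit-foliage errors on
artifact-bearing renders).

Degenerate inputs: a perfectly uniform covered image offers no contrast, so
the decision falls back to absolute brightness — all sky if the uniform
value exceeds the scale midpoint (127.5 on 8-bit, 0.5 for unit floats and
scores), all canopy otherwise. This keeps both classifiers idempotent on
their own binary output and makes an all-canopy frame yield TG = 0.

## Sky grid and scalar descriptors

Gap fractions are accumulated on 24 × 15° azimuth sectors by 18 × 5°
equal-angle zenith annuli; each annulus carries the hemisphere-surface
weight w_i = cos θ_lower − cos θ_upper (Σ w_i = 1), split equally among its
sectors. Every pixel whose centre maps in-field contributes to its cell's
denominator, covered or not, so uncovered area depresses the gap fraction.

- TG = sky pixels / all pixels of a rectangular frame (no weighting).
- CO = Σ gf · w / n_az, the unobstructed fraction of hemisphere area.
- FOV-150 variants zero the gap fraction beyond 75° while keeping the
  weights, so masked area counts as obstructed surface and CO150 ≤ CO by
  construction.

## Site factors

ISF weights each cell by the Standard Overcast Sky radiance at the annulus
midpoint, L(θ)/L_zenith = (1 + 2 cos θ)/3, times cos θ (horizontal sensor)
times the cell solid angle, normalised so an open sky gives exactly 1. The
5° midpoint approximation is accurate to ≲ 0.005 against the closed-form
integral (the 60°-cap value 0.8214 is reproduced within 0.001).

DSF overlays the annual sun track: days 1–365 (no leap years), solar time
every 4 min (no equation of time or longitude — annual *ratios* are
insensitive to a uniform clock shift), declination from the Cooper formula
δ = 23.45°·sin(360°·(284+n)/365), zenith from
cos z = sin φ sin δ + cos φ cos δ cos H. Above-horizon samples carry the
relative beam irradiance E0(n)·cos z·τ^(1/cos z) with eccentricity
E0 = 1 + 0.033 cos(360 n/365) and clear-sky transmittance τ = 0.6
(configurable; constant factors cancel in the ratio). Each sample reads the
gap fraction of the grid cell containing the sun, matching the grid-based
processing chain; a per-pixel oracle path exists in the tests.

GSF = 0.65·ISF + 0.35·DSF, the diffuse/direct split recommended for UK
conditions. The weights are parameters; the identity is enforced to 1e-12
whenever both parents are computed.

## Synthetic scenes

A scene is a set of opaque angular disks; a direction is sky iff it misses
every disk, so the gap function is exact and cheap. Disk-centre zeniths
follow density ∝ sin θ · (θ/90)^1.5, concentrating obstruction toward the
horizon as slant paths through real canopies do. Defaults: 300 disks,
radii uniform 3–12°, artifact fraction 0.03. These were chosen so that the
resulting truth GSF falls around 0.1–0.3 (the modal range for managed
closed-canopy stands), the horizon band (75–90°) is mostly obstructed
(mean gap fraction ≈ 0.03), and varying the disk count from ~50 to ~900
sweeps GSF across roughly 0.05–0.6. Renders colour sky pixels blue with the
red/green channels graded by the SOC radiance (saturated blue channel),
canopy dark green, and a configurable share of canopy pixels bright
yellow-green "sunlit foliage" whose blue channel defeats a brightness-only
threshold — the failure mode the enhanced classifier addresses. Handheld
error is a small random optical-axis tilt plus azimuth twist applied to the
sampled directions, deterministic per named seed stream.

What the simulator does *not* emulate: partial transmission through
foliage, penumbra and mixed pixels, exposure variation, chromatic
aberration, real lens distortion residuals, and sky radiance anisotropy
beyond SOC. Passing the recovery suite therefore demonstrates the internal
consistency and correctness of the geometry/radiometry chain, not
field-level accuracy of segmentation on real photographs.

Validation results computed by the test-suite/acceptance script at the
stated sizes (20 scenes, 1024 px circular renders, 1024 px-wide frames):
circular-pipeline errors ≤ 0.002 on all four descriptors; merged-vs-circular
mean |Δ| ≈ 0.005; diagonal TG exceeds circular CO in 40/40 zenith-loaded
scenes; the enhanced classifier lowers TG relative to the blue-channel
method by ≈ 0.02 on artifact-bearing scenes. Problem sizes were chosen to
make rasterization error negligible relative to the tolerances while
keeping the whole validation run in a few minutes on one CPU.

## Calibration models

Paired records (circular value y, smartphone value x, overstory class OV,
optional camera body and height-from-ground labels) are fitted with the six
fixed-effects structures from y ~ x up to
y ~ x + x:OV + OV + camera + HFG by OLS, and ranked by
AIC = n·ln(RSS/n) + 2(k + 1). The sampling hierarchy (points within stands
within forests) is deliberately *not* modelled with random effects: the
deliverable is the predictive fixed-effects surface, and an optional
stand-level block bootstrap can supply uncertainty where needed. The
Gaussian-identity OLS analogue replaces the original mixed-model machinery;
structures whose categorical terms have fewer than two observed levels are
rejected as degenerate rather than silently reduced. Predictions are
clipped to [0, 1] with a flag.

Simulation at n = 200 records, residual SD 0.03 (the scatter scale of
paired canopy estimates): intercept/slope bias < 0.001; with Table-3-like
slope heterogeneity (offsets 0.2–0.4 by overstory class) AIC prefers the
interaction structure over the plain slope in 100/100 replicates and
recovers the slope ordering (larch, pine steepest; broadleaves flattest) in
every replicate; with homogeneous data the plain structure ranks first in
~86/100 (the remainder go to richer structures through ordinary
chance improvement, bounded by the 2-per-parameter penalty).

## Known limitations

- Only the equidistant projection family; no automatic optical-centre or
  radius detection from image content.
- The enhanced classifier is a declared stand-in with fixed memberships; it
  is monotone and behaviourally validated but not tuned to any camera.
- Site factors are annual relative quantities; no absolute irradiance,
  instantaneous values, leap years or topographic shading.
- Merged-protocol fidelity depends on dark horizons; open stands with
  bright low-elevation sky will show larger merged-vs-circular differences
  than the synthetic defaults suggest.
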