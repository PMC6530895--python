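# Methods

This note documents the models, numerical choices and known limits of the
`echoprey` pipeline. It covers, in pipeline order: the relative-dB scale,
the TVG calibration model, preprocessing, school detection and geometric
correction, the RAPP metrics, the count models, and the synthetic-data
generator that the test suite and acceptance script run against.

## Relative intensity scale

Recreational echosounders store one 8-bit integer per sample; the
manufacturer's mapping to physical units is undisclosed. We declare the
scale `dB = 20·log10(max(count,1)/255)` — full scale at 0 dB, floor at
−48.13 dB (count ≤ 1). Any affine-in-log alternative differs by a constant
offset and gain, which cancels in every downstream quantity: the −35 dB
detection threshold is itself relative, the bottom pick thresholds against
the per-ping maximum, and the TVG fit depends only on the *slope* of
intensity against depth. Consequences of the 48-dB dynamic range are real,
not artefacts of the choice: deep, faint targets fall below the storage
floor, which is exactly the signal-to-noise decay with range the
background-noise remover is designed to handle.

Absolute calibration (Sv, target strength) is out of scope: without source
level and gain functions it is not possible, and no operation here
pretends otherwise — the sphere's target strength is never used, only the
depth dependence of its relative echo.

## TVG calibration

Model: stored intensity of a fixed target at depth z differs from its
depth-independent value by `−ξ·log10(z) − 2αz` for an unknown residual
range coefficient ξ. Candidates are the four standard sonar forms
ξ ∈ {10, 15, 20, 40} (cylindrical spreading, intermediate, volume
backscatter, target strength). For each candidate the 8×1 sphere-region
mean intensities (linear-domain means, as for volume backscatter) are
corrected by `+ξ·log10(z) + 2αz` and the Pearson correlation of corrected
intensity with depth is computed; the candidate with the smallest |r|
wins. Ties within 1e-9 break toward the smaller, least aggressive ξ.
"Correlation" is Pearson's r; the fit requires ≥10 regions spanning ≥10 m
so the statistic is meaningful. If even the best candidate leaves
|r| > 0.2 the fit warns that the true depth dependence may lie outside the
candidate set (e.g. data that are already depth independent).

α comes from the Francois–Garrison (1982) three-term model (boric acid,
MgSO₄, pure water) at the transmit frequency, with sound speed from
Mackenzie (1981). At the study's conditions (200 kHz, ~13 °C, S≈34.5,
pH 8) α ≈ 0.06 dB/m and C ≈ 1500 m/s. Both formulas are standard; any
published alternative agrees well within the correlation test's
sensitivity.

Sphere-region extraction centres an 8-bin vertical window on the
maximum-intensity bin within ±1 m of the annotated sphere depth, skipping
pings with no echo above the storage floor (warning, not error).

## Preprocessing

*Analysis domain.* Samples are usable between the fixed 3 m near-field
line and the per-ping bottom line minus a 0.3 m backstep (≈2 vertical
bins of seabed side-lobe smear). The bottom pick takes, per ping, the
shallowest local maximum deeper than 5 m that is within 10 dB of the
ping's maximum and at least 5 dB above the ping's median, then walks up
to the leading edge of that echo (within 3 dB) — the seabed is where the
return starts, not where the tilted plateau peaks. A 9-ping median filter
enforces continuity and gaps are interpolated; >50% of pings without a
candidate is an unusable transect. Thresholding against the per-ping
maximum makes the pick invariant to the unknown constant offset. The
10 dB window is deliberately narrower than the gap between the seabed
echo and the brightest plausible school (−13 dB relative), so strong
mid-water schools are never mistaken for the bottom.

*Background noise.* The remover assumes noise that is constant at the
receiver, hence rising as `N₀ + TVG(z)` after correction. N₀ is the
minimum over 20-ping × 5-bin cells of (linear-mean cell intensity −
TVG at cell depth). The implied per-sample noise is subtracted in the
linear power domain; samples whose SNR falls below 3 dB are set to the
−999 dB floor sentinel and excluded from every later mean. Floored
samples contribute zero linear power to the averaging cells, so once any
cell is fully floored the estimate collapses to −∞ and a repeat pass is a
no-op — the operation is idempotent. Cell sizes and the SNR threshold are
configuration parameters; the defaults are declared choices, not
recovered settings.

## School detection and beam correction

Detection is the classic threshold/candidate/link/filter sequence:
samples ≥ −35 dB inside the domain form 4-connected components
(4-connectivity prevents single-cell diagonal bridges); components
smaller than the candidate minima are dropped; candidates whose
bounding-box gaps are within 5 m horizontally *and* 2 m vertically merge
transitively (union-find, order independent); linked schools below the
minimum dimensions are discarded but counted. Three named presets carry
the minimum school dimensions: `ground_truth` (3 m length, 1.5 m
thickness) for system characterisation, and `survey_results` (5 m, 2 m) /
`survey_methods` (5 m, 3 m) reflecting two stated survey configurations —
the interface makes the choice explicit rather than silently picking one.

Morphology: L is the along-track extent from first to last member ping
plus one cell width; T the occupied vertical extent; A the summed member
cell area (hence A ≤ L·T, with equality only for filled rectangles); D
the cell-weighted mean depth; mean intensity the linear-domain mean in
dB. The geometric corrections `Lc = L − 2·D·tan(φ/2)`,
`Tc = T − (C/2)(τ/1000)`, `Ac = A·(Lc·Tc)/(L·T)` remove the apparent
enlargement by beam width and pulse length. Schools with non-positive
corrected dimensions are flagged invalid and excluded from abundance
metrics rather than clamped — a clamped zero would still distort the
track-coverage denominator asymmetrically. When D = 0 and τ = 0 the
corrections return the inputs exactly (short-circuited, no float
round-trip). Schools touching the near-field line with length/thickness
aspect ratio above 50 are flagged for review (possible wake or surface
bubbles), replacing manual echogram screening with an auditable rule.

## RAPP metrics

`c.SchA = Σ Ac / distance_km` (m²/km) over valid schools; a switch to
uncorrected A exists. `Prop.Track` places each school's corrected length
on the track as an interval centred at its detected position and divides
the *union* of intervals by track length — overlapping (vertically
stacked) schools are counted once, so the result is a true proportion
≤ 1; plain summation is available behind a flag for comparison. Seasons
derive from survey month (Jan–Mar summer, Aug–Oct winter, otherwise
"other" with a warning). Invalid schools appear in a diagnostics count.

## Count models

`count ~ NB(μ, θ)` with `log μ = β₀ + s(RAPP) + b_region + log(d)`.
Implementation is penalized IRLS:

- *Smooth*: cubic B-spline basis of dimension 4 (the stated ceiling
  against over-smoothing), sum-to-zero identifiability constraint
  absorbed by QR reparameterization so the curvature penalty's null space
  retains the centred linear trend — smoothing never shrinks the linear
  component of the effect. Smoothness λ chosen by GCV
  `n·D/(n − edf)²` on a 9-point log grid (1e−3…1e5).
- *Region effect*: ridge-penalized per-region intercepts on centred
  dummies (the random-effect analogue inside a penalized-regression
  frame), ridge weight chosen jointly with λ by the same GCV on a 6-point
  grid (1e−2…1e3).
- *Dispersion*: θ (variance μ + μ²/θ) profiled by bounded scalar
  likelihood maximisation in an outer loop (4 iterations) around the
  penalized fit.
- *Offset*: survey distance enters as log(d); a doubling of effort with
  correspondingly regenerated counts leaves β₀ unchanged (tested).
- *edf*: trace of the hat matrix; AIC = −2ℓ + 2(edf + 1), the +1 for θ.
  AIC values are comparable only within this implementation — model
  *rankings* are the meaningful output, and they agree with R `mgcv`
  (`gam(count ~ s(x, k=4, bs="cr") + s(region, bs="re") +
  offset(log(d)), family=nb(), method="REML")`) on common data, as does
  deviance explained to within a few points (cross-checked in the test
  suite).
- *Deviance explained*: `100·(1 − D_model/D_null)` with the
  intercept+offset null fitted by the same machinery at the model's θ, so
  a null fit scores exactly 0.
- *Bands*: pointwise ±1.96 SE from the Bayesian posterior covariance
  `(XᵀWX + S)⁻¹` at the selected penalties. These are conditional on λ
  and θ; like GCV-based bands generally they are mildly anticonservative,
  and because errors along the function are coherent (mostly slope
  error), per-replicate coverage is bimodal even at nominal calibration —
  averaged across replicates it is close to 95% for truths representable
  in the basis. A truth whose curvature exceeds what a 4-knot basis can
  express (e.g. a sharply saturating effect) incurs smoothing bias the
  bands do not cover; R mgcv behaves identically on such cases. Recovery
  checks therefore use basis-representable generating smooths and centre
  the truth exactly as the smooth is identified (sum-to-zero over the
  training predictor values).

## Synthetic generator

The generator produces what the pipeline consumes, with conserved truth.
Echograms: an ideal, depth-independent corrected field — Gaussian noise
floor (default −60 dB at source, sd 2 dB), filled-ellipse schools of
uniform core intensity (default −22 dB, within the observed school range
[−34, −13]) with a 240 dB/m falloff outside the boundary, and a bright
seabed streak (−2 dB, 3 bins, decaying tail) — from which the scene's
true TVG gain is *subtracted* before quantizing to 8-bit counts.
Applying the correct TVG downstream restores depth independence, exactly
the situation the calibration stage diagnoses. Grid defaults mirror the
acquisition geometry: 0.25 m along-track, ~0.15 m vertical, 35 m range
window. The steep edge falloff keeps the above-threshold rim of a planted
school inside one cell so detector recovery is testable to a 2-cell
tolerance; softer edges remain available per school. Scenes validate
that every school lies strictly between the 3 m near-field and the
seabed. The default seed 20150522 is recorded in outputs; fixed seeds
give bit-identical records.

Sphere drops place one on-axis echo per annotated depth with raw peak
`K − ξ·log10(z) − 2αz` plus Gaussian noise, K set so the shallowest echo
sits just below full scale — for the 40log form the 3–35 m span (≈46 dB)
nearly fills the 8-bit range, so the deepest echoes quantize coarsely,
exactly as a real store would; TVG-form recovery survives this (≥95% at
1 dB noise, 100 regions, tested at 200 replicates per form).

Survey tables: the 136-survey, 6-region, two-season layout of the study;
distances uniform 3–8 km; per survey the two RAPP metrics share a common
gamma-distributed prey-abundance component (summer-richer) plus
independent variation (empirical correlation ≈ 0.45 — correlated as in
the field, but not collinear, so metric selection is a meaningful test);
counts drawn NB with log-link means driven by one designated metric per
predator. Default effects: dolphins driven by Prop.Track with a
saturating effect of range ≈ 2 on the log scale; penguins by c.SchA
(tanh, range ≈ 2.2); region intercept spreads of ~1–3 on the rate scale;
θ = 1.5 (dolphin) and 2.0 (penguin).

What the generator does **not** emulate: beam-pattern convolution,
multiple scattering, vessel motion and tide artefacts, fish avoidance,
species mixtures, GPS fix error, and mid-survey range/gain changes.
Passing tests therefore demonstrate the *pipeline's* correctness against
its stated models, not field performance of the hardware.

## Problem sizes

Test and acceptance runs use transects of 400–1400 pings × ~235 bins,
300-region sphere drops, 50–200 calibration replicates per generating
form, and 136-survey count tables with up to 100 replicate fits —
desk-scale versions of the study's geometry chosen so the full suite
completes in about a minute on one CPU.

## Known limitations

- The dB scale, bottom-pick settings, noise-remover cell sizes and
  linking distances are declared choices; none are recoverable from an
  uncalibrated store and all are configuration-exposed.
- Smooth bands are conditional on (λ, θ); smoothing-parameter uncertainty
  is not propagated.
- `Prop.Track` union semantics differ from plain Lc summation when
  schools stack vertically; both are computed, union is the default.
- The CSV ingestion boundary assumes the documented export schema; the
  proprietary compressed on-device format is not parsed.
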