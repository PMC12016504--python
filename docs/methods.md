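# Methods

## Measurement model

A photographed assay sample is modelled as a homogeneous colored liquid
whose brightness encodes its state.  Every pixel is converted to HSV by the
standard hexcone formulas (V = max(R,G,B)/255 exactly; S = (max−min)/max
with S = 0 at black; H piecewise, wrapped to [0, 1) — multiply by 360 for
degrees).  Conversion is performed in float64 after an exact division by
255; this keeps the V-equals-max-channel identity bit-exact, which the test
suite asserts against the standard library's converter.

The measurement unit is a square pixel box of even side `s` (default 32)
centred on a chosen point, spanning the half-open ranges
`[r − s/2, r + s/2) × [c − s/2, c + s/2)` in 0-based row-major coordinates.
Boxes that cross the image edge raise an error rather than being clamped:
clamping would silently bias means near tube walls.  Within a box the V
mean and its sample SD (n − 1; the box samples a larger region) are
computed over all s² pixels; a sample measurement is the unweighted mean of
its per-box means, with the SD **across box means** as the spread.  That
spread describes within-image heterogeneity at the sampled points; the SD
across replicate tubes is a different quantity and is obtained by grouping
replicate samples (the `group` column of a series table), never by pooling
pixels.

## Glare handling and point selection

Specular reflections are near-white: bright and desaturated.  A pixel is
flagged as glare iff V ≥ `glare_v_threshold` (default 0.95) and
S ≤ `glare_s_threshold` (default 0.20); both are configurable because
lighting setups differ.  A candidate point is valid when its box lies
inside the region of interest and the flagged fraction within its box is
≤ `max_glare_fraction` (default 0 — total avoidance of reflections).
Automatic selection draws valid centres uniformly at random with a seeded
generator, rejecting failures, with an attempt cap of 1000·n so a
pathological frame fails in bounded time.  The minimum point count defaults
to 12 with 15+ recommended; more points shrink the standard error of the
sample mean roughly as 1/√n, which the suite verifies qualitatively.

## Series quantification

Time series are normalized by subtracting each sample's earliest
measurement (the t₀ entry becomes exactly 0; negative later values are
retained as fluctuation, never clipped).  Because reduced graphene oxide is
darker, V *falls* as reduction proceeds; the analysis layer therefore
defines the reduction signal as `baseline − value` under the default
`signal_direction="darkening"` so that rates, Gompertz fits and the LOD
operate on a positive, increasing signal.  `"brightening"` flips the sign
for assays of the opposite polarity.

- Calibration: OLS of value on concentration restricted to an explicit
  `fit_range` (default 0.06–0.12 g/L).  The plateau above ~0.40 g/L is
  excluded by the user-stated range; automatic breakpoint detection is out
  of scope by design — the plateau is identified by inspection.
- Limit of detection: `(mean + 3·SD)` of the pooled control signals
  (SD with n − 1), divided by the maximum signal detected among
  non-control samples.
- Rate: regression through the origin, slope = Σty/Σt², with
  SE = √(Σ(y − bt)²/((n−1)Σt²)); the origin constraint reflects the
  baseline-subtracted signal being 0 at t = 0 by construction.
- Kinetics: the modified Gompertz form of Zwietering,
  `y(t) = A·exp(−exp(μe/A·(λ − t) + 1))`, fitted by bounded
  Levenberg–Marquardt/trust-region least squares (`A, μ > 0`; tolerances
  1e−14, ≤ 5000 function evaluations, failure raises with solver
  diagnostics).  Default initialisation: A from the data maximum, μ from
  the steepest finite-difference slope, λ from the first time the signal
  exceeds 10% of A.  The inner exponential is allowed to overflow before
  the lag; the outer exponential maps it to the exact limit 0.

## Inference

The two-sample test is the pooled-shift bootstrap: shift both samples to
the pooled mean (x′ᵢ = xᵢ − x̄ + z̄, y′ᵢ = yᵢ − ȳ + z̄), then per replicate
draw n values with replacement from x′ and m from y′ and compute the Welch
statistic t = (x̄ − ȳ)/√(s²ₓ/n + s²ᵧ/m), each arm's own size in its
variance term.  The p-value is the fraction of replicates at least as
extreme as the observed statistic — |t*| ≥ |t| two-sided (default, since
group separation in either direction is of interest) or t* ≥ t one-sided —
at resolution 1/B with no continuity correction.  B defaults to 100,000.
Resamples in which both arms happen to be constant leave t* undefined;
they are excluded from the denominator and counted in the result (this is
conservative and reported, not hidden).  One seeded generator per call,
x-draws before y-draws, makes results bit-reproducible.  The test suite
checks the implementation against exhaustive enumeration of all ordered
resample pairs at n = m = 3 and calibrates its type-I error under the null.

Welch's one-way ANOVA uses the W ratio with weights wᵢ = nᵢ/s²ᵢ and the
Welch–Satterthwaite denominator degrees of freedom; for two groups
W = t² exactly.  Any zero-variance group makes the weights undefined and
raises a degenerate-variance error.  The pooled-variance Student t-test
(df = n + m − 2) and the coefficient of variation (100·sd/mean, reported
to one decimal) support the secondary comparisons.  Significance onset
runs the bootstrap independently per timepoint on a shared grid (per-
timepoint seeds spawned deterministically from the master seed) and
reports the earliest time with p < α; no multiple-testing correction is
applied across timepoints, so under the null each pre-divergence timepoint
still fires at rate ≈ α — onset times should be read with that in mind.

## Synthetic data

The generator renders what the assay's photographs look like, not their
optics: a uniform background at (hue ≈ 0.08 brown, saturation 0.45,
value = ground truth), a horizontal half-period cosine ramp added to V
(peak-to-peak = `gradient_amplitude`, mean-zero, the simplest structured
illumination confound), dark speckle pixels (flocculates) at a given
density and value, glare ellipses painted last at V = 1/S ≈ 0.02, and
per-channel Gaussian noise added in RGB before clipping and 8-bit
quantisation.  Every render returns its ground truth (true value, exact
glare and speckle footprints) so tests never re-derive truth from pixels.
Time courses place the rendered value at v₀ − y(t) (darkening) with
seeded between-replicate noise; the noiseless signal is monotone
non-decreasing by construction.

What this does *not* emulate: camera optics and vignetting, JPEG
compression artifacts, meniscus and tube-wall geometry, settling dynamics
of real flocculates, and correlated (non-Gaussian) sensor noise.  Passing
the recovery tests therefore shows the algorithmic chain is unbiased under
controlled artifact levels, not that any particular camera setup is.

Two quantitative notes on the recovery sweep.  Speckle pixels are part of
the raster the boxes average, so they shift the measured mean by
density·(true_v − speckle_v); the sweep runs at density 0.005 so this
systematic term stays well inside its ±0.01 recovery band.  And because
the illumination ramp is antisymmetric about the frame centre, excluding a
one-sided glare region would skew the average of the sampled points; the
sweep's glare highlight is centred, which is also where tube highlights
sit under an overhead lamp.

## Problem sizes

Defaults used by the test suite and the acceptance script: rendered frames
of 160–300 px per side; 12–30 points per sample; 3 replicates per arm;
17-point time grids over 0–8 h; Gompertz ground truth A = 0.15 value
units, μ = 0.05 units/h, λ = 1.5 h on a v₀ = 0.55 background; bootstrap
B = 2000–100,000 with 1000–2000 outer replicates for calibration checks.
These sizes give stable statistics while keeping the full suite fast on a
single core.

## Known limitations

- The glare criterion is threshold-based; colored reflections (bright but
  saturated) are not flagged.  Thresholds are exposed for such setups.
- Calibration requires the user to state the linear range; no automatic
  plateau detection.
- The degenerate-resample exclusion makes the bootstrap p conservative for
  tiny, nearly-constant samples (the excluded mass is reported).
- Times are taken from an explicit column or the simulate naming
  convention; no timestamp inference from image metadata.
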