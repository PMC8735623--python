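# Methods

This note documents the models, estimators, numerical conventions and
design choices behind macroquant, in the spirit of a methods section: it
states what the code computes and under which assumptions, not results.

## Trajectory analytics

**Model of the data.** A track is one nucleus's time-ordered positions
(μm) at a nominally uniform frame interval; live movies in this assay
are acquired every 39–41 s, so `Trajectory` tolerates up to 5% relative
jitter and every velocity uses its own interval `dt_k` rather than a
nominal frame time. Velocities are reported in μm/min.

**Estimators.** Per-track mean speed is the arithmetic mean of
instantaneous speeds. Directional persistence is the mean cosine of the
angle between consecutive instantaneous velocities; the group
persistence index is the *unweighted* mean of per-track persistence, so
long tracks do not dominate. Indexing convention: with `l`
instantaneous velocities (= positions − 1) the sum runs over the `l − 1`
consecutive pairs — the only reading that makes the normalizer
`1/(l−1)` well defined. "Minimum duration of 15 time frames" is read as
≥ 15 positions, inclusive at the boundary.

**Zero-magnitude velocities.** The angle to or from a zero vector is
undefined. Such pairs are excluded from numerator and denominator
rather than scored 0, which would bias the index toward 0 for pausing
cells. A track with no valid pair returns NaN (an undefined-result
signal, distinct from an error) and is dropped from the group index.

**Gating and alignment.** Zones are axis-aligned rectangles with
half-open intervals `[min, max)`; a track belongs to the zone containing
its mean x/y position (the anatomical regions of a real embryo are
approximated by caller-supplied rectangles). Movies are aligned to the
AP axis by a rigid 2D rotation, under which all statistics are invariant
(tested to 1e−9).

**Crossing time.** The germband-crossing time runs from a caller-
supplied start event to the first frame at which any track's x
coordinate is on the opposite side of a vertical boundary from its
initial side; event times have frame resolution (no interpolation). The
start event — cells aligning in an arc at the tissue edge — is a human
judgment; a heuristic (`estimate_alignment_time`: first frame with ≥ k
tracks within d μm of the boundary) is provided but never applied
implicitly.

## Linescan enrichment

**Window geometry.** The membrane is the global argmax of the
membrane-marker channel (ties to the smaller position; no sub-sample
refinement, matching argmax-of-profile practice). Windows on the
inside→outside axis: membrane `[c−0.4, c+0.4]` μm, outside flank
`(c+0.4, c+2.4]`, inside flank `[c−2.4, c−0.4)`. Background = mean raw
reporter over the outside flank, subtracted from the entire profile.

**The central interpretive decision.** "Integrated intensity within the
window" is computed as the *window mean* (integral divided by window
length), so the membrane and cytoplasm terms share units and ratios of
order 1–2.5 are meaningful; a raw-sum reading would scale the ratio by
the sample-count ratio of the windows (9/20 at dx = 0.1 μm).

**Discretization.** A sample belongs to a window by its position with a
1e−9 μm edge tolerance, so grid points landing exactly on window edges
bin deterministically at dx = 0.1. Window means are equal-weight sample
means; relative to continuous integrals this widens each window by half
a sample at each end, a few-percent effect that is irrelevant to
ratio-vs-ratio comparisons because generator calibration and analysis
share the same grid. Negative corrected intensities are allowed
(background is an estimate); only a non-positive *cytoplasmic mean*
excludes a profile, and exclusions are always counted and logged.

**Image extraction.** `extract_line_profile` samples both channels
identically along the line at one-pixel steps, averaging `width_px`
(default 8) bilinear samples across the perpendicular; the footprint
must stay inside the image. Pixel size defaults to 0.1 μm.

**Junction peaks.** `fit_junction_gaussian` fits
`a·exp(−(x−c)²/2σ²) + b` by least squares with deterministic
initialization (amplitude = max−min, center = argmax, σ = L/4,
offset = min), capped at 500 function evaluations; non-convergence or
σ larger than the line raises a fit failure. The fitted peak (a + b) is
normalized against the mean staining of a reference region (~50×50 μm)
of the same embryo.

## Comparison pipeline

Per-embryo intensity = unweighted mean of its ROI means. Batch
normalization divides every embryo by its batch's control mean, making
the per-batch control grand mean exactly 1 and cancelling any
multiplicative session gain; every batch must contain a control embryo.

**Outlier screen.** ROUT (the FDR-based screen in GraphPad Prism) has
unpublished internals; macroquant implements a deterministic
approximation: residuals from the median are standardized by
MAD·1.4826·n/(n−0.8) (small-sample-corrected), converted to two-sided
t(n−1) tail probabilities, and flagged by a Benjamini–Hochberg step at
maximum FDR Q (default 10%). With zero robust scale, points at the
median get p = 1 and deviants p = 0, so homogeneous data yield no
outliers while gross deviants in otherwise constant data are flagged.
Flags are monotone in Q and Q = 0 flags nothing. The screen is applied
per group after normalization. This is an approximation of ROUT's
intent, not a reimplementation.

**Effect arithmetic.** `percent_change(ref, x) = 100·(ref − x)/ref`
(positive = reduction); `effect_fraction(control, reference, x) =
100·(control − x)/(control − reference)`. Printed-style integers round
halves away from zero; the unrounded value is always available.

## Synthetic data: what it emulates and what it does not

**Tracks.** Constant step speed (so speed recovery is exact and
decoupled from persistence) and von Mises turning. Calibration uses the
2D closed form E[cos Δθ] = I₁(κ)/I₀(κ), inverted by monotone bracketing
+ Brent to |error| < 1e−6 on the mean cosine; κ ≥ 1e6 is treated as the
straight-line limit and κ = 0 as uniform turning. Tracks are planar
(dim = 3 embeds the same walk at z = 0) because the Bessel calibration
is a 2D identity; the persistence estimator itself is
dimension-agnostic. Real tracks have variable speeds, pauses, and
speed–turn coupling; the generator deliberately omits these, so recovery
tests validate the estimators, not biological realism.

**Profiles.** Membrane channel: Gaussian(center, σ_mem) on a constant
floor. Reporter: `bg_out + cyto_level·logistic + mem_amp·Gaussian +
noise`, where the inside plateau decays through a logistic of width
σ_mem centered at the membrane — a hard step would make window means
jump with sub-sample shifts of the center. Defaults: 8 μm line,
dx = 0.1 μm, center 4 μm, σ_mem 0.25 μm, plateau 100, background 20.
Because the membrane window straddles the cell edge, the amp-0 ratio is
about 0.5, not 1 — consistent with sensor ratios below 1 under strong
perturbation. `calibrate_profile_amplitude` solves ratio(A) = target by
bracketing + Brent *through the analysis pipeline itself*, so
calibration followed by analysis is an identity on the target to 1e−4;
targets below the amp-0 floor are unreachable and raise. The model has
no PSF blur, bleed-through, or membrane-position jitter.

**Shapes and intensities.** Independent normal draws: lengths/widths
truncated at > 0.1 μm; per-embryo intensities clipped at 0 and assigned
round-robin to batches. Clipping slightly raises the mean of a
low-mean/high-SD group (≈ +0.02 for mean 0.47, SD 0.4), which shifts the
recovered percent reduction by ~2 points — visible in the recovery
tests' tolerances.

## Presets and problem sizes

`presets.yaml` bundles the printed values (speeds, persistence indices,
mem/cyto ratios, intensity and shape moments) with a provenance comment
per entry; shape preset *means* are synthetic choices (the study prints
only SDs and percent changes) marked as such in the file. Recovery
runs use group sizes a desk-scale study of this kind would have —
100×60-step tracks for speed, 500×30 for persistence, 50 noiseless
profiles, 50 cells/group for shapes, 20 embryos/group for intensities.
At those sizes the stochastic recoveries carry sampling SEs of ~0.01
(persistence), ~5 points (length change) and ~8 points (intensity
reduction); the deterministic stages are seed-independent.

## Known limitations

* No nucleus detection/linking, segmentation, or automatic line
  placement: the pipeline starts from centroids, profiles and
  pre-measured shapes.
* The ROUT approximation will not match Prism flag-for-flag on
  borderline points.
* Zones are rectangles; irregular anatomical boundaries must be
  approximated by the caller.
* Persistence and speed are computed in the coordinates given; 3D
  tracks are supported, but the synthetic calibration target is 2D.
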