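# Methods

This note records the models, parameter choices and numerical decisions
behind `spinetrace`, and what the synthetic benchmark does and does not
demonstrate.

## Imaging model and preprocessing

Input is a two-channel video: a *structure* channel (cell fill) used for
all segmentation, and a *protein* channel (tagged protein) used only for
density measurements. Intensities are handled as floating fractions of
full scale; 16-bit TIFF is the on-disk format, which accommodates 12-bit
camera data without committing to its bit depth.

The structure channel is cleaned per frame with a white top-hat
(disk radius 50 px at native resolution — large enough to pass dendrites
and spines, small enough to flatten out-of-focus background), a 3×3
median, and exact empirical-quantile histogram matching against frame 0,
which undoes multiplicative photobleaching. Frames are then upscaled ×4
with bicubic interpolation (128×128 → 512×512); the top-hat acts before
upscaling so the disk keeps its physical meaning. The protein channel
receives *only* histogram matching and upscaling: morphological filtering
would distort the relative intensities that the density and flux
measurements depend on, and the temporal enhancement below is likewise
never applied to it.

For radii above 16 px the top-hat structuring disk is decomposed into a
footprint sequence (mean deviation from the exact disk ~4·10⁻⁴ of full
scale on smooth images, two orders of magnitude faster). The exact disk is
used at small radii.

## Temporal enhancement and foreground

The temporal maximum intensity projection (TMIP) is the pixelwise maximum
over all frames; min–max normalized it becomes a per-pixel weight in
[0, 1], so enhancement can only attenuate. The foreground is
`enhanced > m · otsu(enhanced)` with multiplier m = 0.3 by default
(useful range 0.2–0.4: the plain Otsu cut loses dim spine tips).
Components under 20 px are discarded and interior holes are filled —
the imaged structures are solid, so holes are noise artifacts.

## Dendrite segmentation

1. **Skeleton.** The foreground is thinned and side branches shorter than
   `trim_length` = 40 px are pruned. The value must exceed the skeleton
   length of a spine (20–50 px at the analysis scale) so spines do not
   contribute endpoints; the dendrite path itself is an order of magnitude
   longer.
2. **Endpoints and seed chain.** The two skeleton pixels farthest apart
   *along* the skeleton anchor the backbone (double BFS sweep; geodesic
   rather than Euclidean distance so U-shaped dendrites keep tip-to-tip
   orientation; the sweep runs over all pixels because thinning can end a
   path in a 2-px diagonal stub with no degree-1 pixel). The chain is
   refined by recursive subdivision: wherever the skeleton path deviates
   more than d = 15 px from the chord between two seeds, the farthest
   pixel becomes a new seed.
3. **Directional sweeps.** For each consecutive seed pair the flow
   direction is quantized to 8 compass directions; growth from one seed
   admits only the three 3×3 steps within ±45° of the flow, growth from
   the other the three opposite steps, and the two reachable sets are
   intersected. Each sweep is seeded with the full mask cross-section
   through its endpoint (a point seed degenerates to a lens pinched at
   both ends). Thin protrusions perpendicular to the flow cannot be
   climbed — every admitted step advances along the flow — so spine necks
   drop out, while a small cone at wide spine bases remains. The rounded
   end caps beyond the skeleton tips are dendrite by construction and are
   stamped explicitly (disk of 1.6× the local half-width at each tip),
   since no sweep covers them.
4. **Contour low-pass.** The region's closed contour, traversed as a
   complex sequence, is truncated to the lowest `keep_fraction` = 0.02 of
   its Fourier descriptors and refilled. At 512×512 a dendrite contour has
   2000–3000 samples, so 0.02 keeps ~25–60 harmonics: enough to follow the
   curve, few enough to erase spine-base cones and seed-point kinks whose
   wavelengths are 50–100 px. The smoothed mask is intersected with the
   sweep union — smoothing may only remove sweep artifacts, never annex
   spine territory — and with the foreground.

## Spine segmentation

The Euclidean distance of every foreground pixel to the nearest dendrite
pixel peaks at spine tips. Along the ordered foreground contour
(Moore-neighbor tracing) the distance profile is scanned for regional
maxima with plateau merging; a maximum seeds a spine if it exceeds
`max(min_spine_height, baseline + min_prominence)` where the baseline is
the profile median — the contour runs mostly along the shaft at the halo
clearance left by the low foreground threshold, so the median estimates
that clearance automatically. Defaults: floor 3 px, prominence 5 px. The
prominence matters: halo ripples and residual sweep artifacts reach ~6 px
above the shaft at 512×512, while the smallest realistic spine protrudes
well over 10 px at this scale.

The spine's contour arc is walked from the seed in both directions until
the profile descends back to the baseline (plus 1 px), with a safety
radius of three seed heights; the arc endpoints — where spine meets
dendrite — are joined by a straight base line (Bresenham), the closed
curve is filled (4-connected hole filling so the 8-connected boundary is
tight) and clipped away from the dendrite. Arcs of fewer than 3 pixels are
degenerate and dropped. Morphology scalars: area, height (max distance to
dendrite inside the mask), width (base-line length), mean structure
intensity.

**Splitting.** Spines merged at the base share one arc whose profile shows
two maxima around a valley; if the valley is below half of either flanking
maximum, a dividing line runs from the valley pixel to its nearest
dendrite pixel and is excluded from both children (1-px gap). Applied
recursively.

**Declumping.** Severely overlapping spines are separated by a
marker-controlled watershed. Intensity extrema inside the mask (lightly
smoothed by masked Gaussian, σ = 1) are detected with an h-prominence of
0.1 intensity fraction — plain regional extrema would cut flat or noisy
spines on interpolation ripple. Maxima pairs whose axis is not parallel to
the local dendrite tangent (tolerance 30°) are connected by a straight
line, provided the line avoids minima and does not dip below its
endpoints by more than the prominence (a ridge stays a ridge); minima
pairs are connected symmetrically. The composite marker image (background
and minima 0, maxima 255, rest 127) is inverted and flooded from the
maxima with a watershed line, which splits the mask.

## Tracking and flux

Spines are anchored to the dendrite, so association needs no motion
model: each frame's segments join the track whose last known mask they
overlap most (Jaccard), greedily one-to-one, with a new-track threshold of
0.1; tracks may skip frames and re-associate at the last known location.
Integrated density is the masked sum of the protein channel (never
TMIP-enhanced), robust to area changes. Flux between consecutive observed
frames is Δρ/Δframes; the sign gives the direction (in/out through the
spine neck, the only boundary), the source term is zero (the protein is
neither produced nor consumed in the spine on these timescales). A
dead-band (default 0) can absorb sensor noise in the in/out accounting.
Flux telescopes: the series sums to ρ(last) − ρ(first).

## Spine energy images and classification

Aligned masks are produced by rotating each spine base-down about its
base-line midpoint (inverse-mapped nearest-neighbor sampling, which leaves
no rotation holes), cropping, and pasting into a 10×10 frame base-down
and horizontally centered with preserved aspect ratio (silhouette
convention). The SEI is the pixelwise mean over the track. The uniform
LBP uses the square 8-neighborhood at radius 1 with neighbor ≥ center;
only this rotation-variant dialect yields 58 uniform patterns + 1 pooled
bin = 59 features, and the histogram sums to the 64 interior pixels.
Feature vectors are the track's SEI-LBP histogram plus the per-frame (or
per-track mean) area, height, width and mean intensity, 63 dimensions;
the morphology block is z-scored inside the classifier pipeline with
training-fold statistics only.

Classifiers: linear discriminant analysis (Gaussian per class), k-NN with
k = 5 (Euclidean), and error-correcting output codes as one-vs-one linear
SVMs (C = 1; three binary learners for three classes). Cross-validation is
stratified 10-fold repeated 20 times with reshuffling; folds are capped at
the smallest class size. The classical baseline is a decision-tree cascade
on raw measurements: height/width < 1 → stubby; head/neck width ratio
> 2 → mushroom; else thin — thresholds are configuration, not claims.

Benchmark accuracies are computed per track (one feature vector per
track, morphology averaged over frames): per-segment rows from one track
are nearly identical, and scoring them under plain k-fold would leak
track identity across folds.

## Synthetic data

The generator emulates the study conditions: 128×128 two-channel frames
at 3-min intervals, a spline-interpolated curved dendrite (width 7 px)
rasterized by distance-to-curve, spines of the three classes placed on
the curve with class-consistent geometry (mushroom head > neck; stubby
without a neck; thin neck longer than head), per-frame sway as a rotation
about the base following one sine period, protein levels per spine as a
time profile (constants or linear ramps), multiplicative photobleaching
(default 0.98 per frame), additive background haze (0.05) and Gaussian
noise (σ = 0.02 of full scale; the camera's noise statistics are not
specified, so Gaussian is a parameterized stand-in). Ground truth is the
noise-free rasterization: per-frame dendrite and per-spine masks (pairwise
disjoint, spine masks exclude the dendrite) and the noise-free integrated
density series. Everything is driven by one seed; identical specs render
bit-identical videos.

Canonical scenes used in tests and the acceptance script: `six_spine`
(S-curve, 2 spines per class, 12 frames, noise-free), `six_spine_noisy`
(same geometry at σ = 0.05 with bleach 0.99 and background 0.05),
`u_shape` (strongly curved dendrite, 4 frames), `flux` (10 frames,
protein ramps 0.2→0.8 on half the spines and 0.8→0.2 on the other half,
noise- and bleach-free), `bare` (straight spineless dendrite). The
classification benchmark simulates 60 tracks per class of 12 frames on a
64-px canvas with geometry drawn from class ranges
(neck length / neck width / head diameter in analysis-scale px —
stubby: 0–1 / 8–14 / 10–16; thin: 18–30 / 3–5 / 4–7;
mushroom: 6–14 / 4–7 / 12–18), random orientation, sway of 3–10° with
1° jitter, and 8% boundary-pixel flip noise.

What passing these benchmarks does *not* show: real videos have textured,
spatially correlated background, crossing neurites, z-drift, and spines
whose geometry drifts between classes mid-track; none of these are
simulated. The synthetic results demonstrate internal correctness and
parameter recovery under the stated imaging model, not field performance.

## Problem sizes and determinism

Test-bench scenes use 12 or fewer frames at 128×128 (analysis at
512×512), six spines per scene, and 180 benchmark tracks; these sizes
exercise every code path while keeping a full test run around a minute
and the acceptance script under two. All randomness flows from explicit
seeds (scene seed, benchmark seed, CV seed); pipeline reruns are
bit-deterministic. Ties: plateau extrema seed at the plateau midpoint;
greedy matchings break ties by descending overlap then input order;
endpoint selection breaks BFS ties lexicographically.

## Known limitations

- Branched spines and 3D geometry are out of scope; the pipeline is
  strictly 2D and three-class.
- The contour-arc extraction under-covers very squat, wide spines on the
  concave side of a curved dendrite (the dendrite sweep claims part of
  the base); detection still succeeds at the 50%-overlap rule in the
  benchmark scenes, but mask areas for such spines are biased low.
- The in-pipeline classifier is trained on the synthetic shape library;
  transferring it to real data would require retraining on labeled
  spines from the same imaging setup.
- Flux is reported per frame interval as a proportionality; absolute
  units would require calibration of intensity per molecule.
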