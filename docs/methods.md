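# Methods

## Pipeline model and assumptions

The pipeline assumes one leaf blade photographed against a plain,
contrasting background, forming a single connected foreground region
after thresholding.  Everything downstream operates on the blade's
closed single-pixel boundary; petioles, shadows and multi-leaf scenes
are out of scope.

**Segmentation.**  Grayscale conversion uses the BT.601 luma weights
(0.299, 0.587, 0.114) with round-half-up.  The Otsu threshold is found
by exhaustive search over all 256 integer levels of the between-class
variance `w0·w1·(mu0 − mu1)²`; ties go to the lowest level.  Foreground
polarity is chosen automatically as the class with fewer image-border
pixels (a centred leaf touches the border less than its background);
a `polarity` setting overrides this.  A morphological closing with a
radius-2 disc (the mask is padded first, so the operation equals the
set-arithmetic closing against an unbounded background and is
extensive) removes pinholes and hairline breaks.

**Scale normalisation.**  Curvature is measured in 1/pixels, so every
curvature threshold is resolution-dependent.  Masks are rescaled so
the blade's major axis is 512 px (configurable `normalize_size`)
before contour extraction; the 0.05 px⁻¹ sinus threshold is defined at
this scale.

**Contour.**  Moore-neighbour tracing with Jacob's stopping criterion
yields an ordered 8-connected pixel chain on foreground pixels
adjacent to background.  Orientation is normalised to positive
shoelace area in (x = col, y = row) coordinates, so the interior lies
on the left of travel; that convention fixes the sign of curvature
(positive = bending toward the interior) and the interior side used by
the sinus search.  A Canny-based route (`contour_from_gray`, high/low
thresholds 0.35/0 as fractions of the intensity range) is available
for grayscale-only operation; on clean segmentations it agrees with
mask tracing.

## Corner detection (curvature scale space)

Coordinates are smoothed with a unit-sum Gaussian of width δ
(periodic convolution for closed curves, reflective for open), and
derivatives come from Gaussian-derivative kernels at the same width.
The kernel is truncated at 6σ rather than the usual 4σ: the truncated
second-derivative kernel has a small residual response floor that, at
4σ, biases curvatures of order 10⁻² by up to tens of percent — exactly
the range the sinus classifier thresholds.

Stages, with the working parameter set δ = 4, C = 1.5, T_angle = 162°,
Gap_size = 3, Endpoint on:

1. open/closed classification by endpoint gap (closed iff ≤ Gap_size,
   boundary inclusive);
2. candidates = strict local maxima of |κ| (plateaus take their
   central index; circular neighbourhood on closed curves);
3. non-maximum suppression within 2δ samples.  At δ = 2 pixel
   quantisation fragments one corner into several near-equal maxima a
   few samples apart; unmerged, they truncate each other's regions of
   support and the next filter deletes the whole cluster.  Greedy NMS
   keeps the strongest member of each cluster;
4. round-corner removal: keep a candidate iff |κ| ≥ C × mean |κ| over
   its region of support (the span between its neighbouring
   candidates; the whole curve for a lone candidate);
5. false-corner removal: compute each candidate's opening angle from
   rays to the contour points 12 samples away on each side and remove
   it if the angle strictly exceeds T_angle (a candidate exactly at
   T_angle survives).  The arm length is a fixed 12 samples, not a
   multiple of δ: with δ-scaled arms a blunt corner's measured turning
   grows with δ and the filter *admits* corners only at coarse scales,
   which inverts the expected monotone decrease of corner count in δ;
   with fixed arms, stronger smoothing can only widen angles, so the
   count is non-increasing in δ (this is also what the scale-sweep
   acceptance experiment checks);
6. open curves only: endpoints farther than 3δ samples from every
   surviving corner are appended as corners when `endpoint` is set.

Guidance for δ follows the density of the serration: dense fine teeth
need a small δ (2–4) to resolve adjacent corners; sparse large teeth
tolerate (and benefit from) δ = 5–7, which suppresses margin noise.
δ = 4 is the default working point.

## Tooth points

A corner is a **tooth apex** iff the disk of radius L centred on it
contains strictly fewer foreground than background pixels (disks
crossing the image border are clipped).  L is never fixed by the
source description; the default is `max(5, round(1.5 δ))` px — large
enough to dominate single-pixel boundary roughness at the working
smoothing scale, small enough to stay local to one tooth.  The strict
inequality sends straight-edge points (fraction ≈ 1/2) to
"not convex".

The **sinus** between two adjacent apices is the contour point of the
intervening segment at maximum perpendicular distance from the
apex–apex chord, counted only on the interior side of the chord (so a
bulging lobe between two apices is never mislabelled a sinus; such a
pair simply has no sinus).  Ties take the first point along the
segment.  Fewer than two apices means an entire (toothless) margin and
an empty tooth-point set.

## The five characters

* **Tooth length** = perpendicular distance from the apex to the chord
  through its two flanking sinuses.  Lengths strictly greater than
  twice the mean are outliers and removed; the rest are divided by
  their maximum.
* **Orders**: with `n_short` = number of normalised lengths strictly
  below 0.5, the leaf has two orders iff `n_short` strictly exceeds
  half the tooth count; order-1 teeth are those at or above 0.5.  The
  0.5 cut is also used for the per-tooth assignment (an adjacency
  heuristic — "longer than both neighbours" — is a possible
  alternative but is unquantified and not implemented).
* **Spacing**: Euclidean distances between cyclically adjacent apices;
  regular iff min > 0.6 × max, strictly — equality is irregular.  With
  exactly two apices both cyclic chords coincide and one distance is
  reported.
* **Sinus shape**: mean |κ| (smoothed curve, δ = 4) over the sinus
  points; angular iff strictly above 0.05 px⁻¹.  This reproduces all
  eight published reference values (0.087059 … 0.061088 angular;
  0.043190 … 0.009013 rounded).
* **Tooth shape**: each flank arc (apex A to sinus E, the shorter
  contour span) is rotated so the chord AE is the abscissa and fitted
  with a quadratic.  |a| < `st_tol_factor`/chord means straight.  The
  default `st_tol_factor` is 0.12 — the printed rule ("coefficient
  equal to zero") admits no tolerance, so the default is a design
  choice: it is calibrated such that a lobe clearly beyond the straight
  tolerance can still stay below the corner detector's sensitivity;
  larger values force lobes so big the detector reports them as extra
  corners and tooth counts break.  Otherwise chord–arc crossings are
  found with 1 px hysteresis (sign flips where |offset| ≤ 1 px are
  flutter, not crossings).  No crossing: the chord–arc region is
  mostly leaf → cv, mostly background → cc.  One crossing at C: region
  P (A..C, apex side) and Q (C..E, sinus side) are labelled by
  majority pixel class; P leaf & Q background → rt (the flank bends
  back toward the apex), the reverse → fl.  Multiple crossings (rare)
  use the one nearest the arc midpoint; degenerate cases (both regions
  the same class, empty regions, arcs under 4 points) fall back to the
  no-crossing rule or to st.  Region pixels are counted by polygon
  scan fill of the arc closed by the chord.
  The leaf-level label is the majority over flanks, ties broken by
  cv > st > cc > fl > rt.

Because the P/Q rule is anchored to the apex end of the arc, the
labels are invariant under rigid motions *and* mirroring of the image;
swapping which arc end is treated as the apex exchanges fl and rt.

## Synthetic leaves

The generator builds leaf outlines as simple polygons in image
coordinates: an elliptical blade (default semi-axes 235 × 170 px on a
640 px canvas), apex vertices at `tooth_amplitude` above the mean of
their two neighbouring sinus radii (anchoring the rise to the local
blade, not the global ellipse, keeps the notch V-angle uniform on an
eccentric blade), sinus vertices on the ellipse at the mid-angles.
Flanks are chords plus a displacement normal to the chord:

* st: none; cv/cc: a sextic bump `±0.08·chord·64 w³(1−w)³` (C² at the
  ends, so the vertex geometry is untouched); rt: a quintic
  `5.5·chord·w²(1−w)²(w − 0.4)` — a ~4 px inward dip near the sinus
  and a broad outward bulge toward the apex crossing the chord exactly
  once; fl: the same S mirrored along the flank.

Angular sinuses keep the sharp vertex; rounded ones get a tangent
circular fillet (radius 42 px, cut capped at 30% of the flank).
Rendering is a 4× supersampled polygon fill downsampled to an
anti-aliased alpha map, dark leaf (≈45 gray after the luma weights) on
a light background (≈215), plus seeded Gaussian pixel noise σ = 3, so
Otsu is exercised non-trivially.  Identical spec + seed give
bit-identical images.

**Separation buffers.**  The generator asserts, at build time, that
the realised geometry sits clear of every decision boundary: mean
sinus curvature at δ = 4 ≥ 0.060 px⁻¹ for angular and ≤ 0.033 for
rounded (the classifier threshold is 0.05); regular spacing with
min/max chord ratio > 0.63 and forced-irregular with < 0.55 (rule
boundary 0.6); two-order length patterns with strictly more than half
the teeth short (first order goes to `n//3` evenly spread teeth —
strict alternation puts exactly half below the cut and can never
satisfy the printed rule).  Specs violating a buffer raise instead of
silently producing borderline truth, so downstream classification
failures indicate pipeline bugs, not marginal geometry.
`generate_suite` retries a rejected jitter draw at deterministically
incremented seeds.

**Geometric feasibility constraints.**  Not every character
combination is constructible at margin: (a) a sharp V needs the notch
turn to beat the blade's own tangent turning across the inter-tooth
gap, so angular sinuses require roughly nine or more teeth at
realistic amplitudes; (b) the S-shaped flank styles need long flanks
(sparse teeth), so rt pairs with rounded sinuses and fl — whose
outward lobe near the sinus pinches the notch — with angular ones;
(c) cv/cc bulges adjacent to a rounded fillet contaminate the
curvature class margins at desk-scale flank lengths, so cv/cc pair
with angular sinuses.  The canonical 50-template suite therefore
covers both sinus styles and all five flank styles (each ≥ 5 times),
tooth counts 8–40, one- and two-order leaves and regular/jittered
spacing, but not the full character cross product.

**What the generator does not emulate:** venation and surface texture,
petioles, lobed or entire margins, perspective distortion, uneven
illumination, and natural tooth-size variation beyond the two-order
pattern.  Passing the recovery experiments therefore demonstrates the
pipeline's correctness on clean, margin-buffered geometry, not its
robustness to field photographs.

## Validation experiments and problem sizes

The acceptance script and test suite run, from scratch: the published
sinus-label reproduction (8 values); a δ sweep over {2, 4, 5, 6, 7} on
a 20-leaf serrate (angular-sinus) suite checking the corner count is
non-increasing per leaf — serrate leaves mirror the original sweep's
material, and rounded-sinus margins are excluded because their corners
are marginal detections whose counts can flicker ±1 across scales (a
known limitation); ground-truth recovery of all five characters on a
50-leaf suite; oracle equivalence for Otsu (100 random images),
closing (20 random 32² masks) and the sinus search (every apex pair of
a 15-leaf suite); curvature against 1/r on circles r ∈ {20, 50, 100}
and against the ellipse closed form (a = 60, b = 30); the three strict
rule boundaries; and rotation/mirror invariance on 6 leaves.  The
sizes keep the full run around half a minute on one CPU while leaving
each experiment statistically meaningful.

## Known limitations

* Tooth counting equates teeth with convex CSS corners; gentle convex
  lobes just above detector sensitivity would count as teeth, exactly
  as in the source method.
* The 0.05 px⁻¹ sinus threshold is tied to the 512 px normalisation;
  analysing unnormalised images shifts the effective boundary.
* The convexity disk radius L is a heuristic default; extremely fine
  serrations (inter-apex distance < 2L) can leak neighbouring teeth
  into the disk.
* Flank labels on very short arcs (< 4 points or chord < 4 px)
  default to straight.
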