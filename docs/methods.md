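# Methods

## The stimulus model

An FAO stimulus is a 384×384 8-bit image containing one 7-pixel line segment
at every site of a hexagonally close-packed lattice: 16 px center-to-center
horizontally, 14 px vertically, alternate rows shifted by 8 px. Segment
centers keep a 3-px margin (half the segment length) from the canvas edge so
no segment is ever clipped; with the default geometry this yields 27 rows
alternating 24 and 23 columns — 635 sites. At a 10° viewing subtense each
element subtends 0.18° and neighbors are 0.42° apart, a ~2:1
spacing-to-size ratio typical of contour-integration displays.

An *object* is a feature list: a subset of sites with assigned orientations.
At render time the remaining sites are filled with segments at one random
background orientation, the lines set to 255 and everything else to 128.
Because every segment lights exactly `segment_len_px` pixels regardless of
orientation (unit steps along the dominant axis, the minor coordinate
rounded), all stimuli under one grid share the identical pixel-value
histogram: mean luminance, RMS contrast, element count and line-termination
count are matched exactly, not approximately.

## Featurization

Source images are scaled so their longest dimension is 87.5% of the canvas
(336 px), converted to grayscale by the unweighted RGB mean, and centered on
a canvas filled with the modal intensity of the scaled image's border (so
white-background drawings and gray-background photographs both pad
seamlessly). Orientation content is estimated with frequency-domain
log-Gabor quadrature filters:

* 8 orientations, 0° to 157.5° in 22.5° steps, measured counterclockwise
  from horizontal in the viewer's frame;
* 4 log-spaced center frequencies spanning 24–120 cycles/image;
* radial sigma ratio 0.745 (≈1-octave bandwidth), angular sigma 17°
  (moderate overlap between adjacent 22.5°-spaced bands);
* DC exactly zero, so uniform intensity offsets never create features.

Only the frequency range and the orientations are fixed by the stimulus
design; the scale count and bandwidths are exposed on `OrientationBank`.
Keeping a single frequency half-plane per orientation makes the inverse
transform complex-analytic, so the squared response magnitude is a
phase-invariant local energy. Per site, energies are summed over scales;
sites whose total energy strictly exceeds 0.1 × the 99th-percentile site
energy are deemed to contain object content and receive their argmax
orientation (ties break to the lowest orientation index). The percentile
reference makes the objectness criterion scale-free across line drawings
and photographs; the threshold is configurable.

On rendered stimuli the same machinery recovers planted orientations
essentially perfectly (the round-trip test requires ≥90%; measured recovery
on clustered random feature lists is 100%), which validates the
orientation-convention bookkeeping between the raster (y-down) and viewer
(y-up) frames.

## Quality control

Two automatic rules, both strict as stated:

* **count filter** — fail iff `n_features < 80` (80 passes);
* **disjointedness filter** — the object's segments (background excluded)
  are dilated with a 16×16-px square, connected components are labeled with
  8-connectivity, and the candidate fails iff there are more than 5 regions
  (5 passes). With this kernel and the 16/14 spacing, 4- vs 8-connectivity
  gives identical verdicts on all test fixtures, so the choice is
  uncritical.

## Stimulus statistics

* **Orientation distribution**: proportions over all 635 elements (object
  plus background).
* **Relative orientations**: every unordered adjacent pair (the hexagonal
  neighborhood is defined geometrically as all sites within 1.05·dx of a
  center, which reproduces the 6-neighborhood under the 16/14 anisotropy)
  is classified once. With Δ the minimal angular difference of the two
  orientations and φᵢ the minimal angle between element i and the
  center-to-center direction: Δ=0 and min φ ≤ 22.5° → collinear; Δ=0
  otherwise → parallel; Δ=90° → orthogonal; intermediate Δ with
  min φ ≤ 22.5° → acute; otherwise obtuse. The category names follow the
  colors conventionally used for such histograms; only the five category
  labels are fixed, the φ-based acute/obtuse disambiguation is this
  package's definition.
* **Object region**: the QC dilation of the object's segments,
  hole-filled, mapped back to lattice sites — one shared definition of the
  object's (possibly concave) perimeter for QC, density and convexity.
* **Density**: fraction of region sites whose element orientation differs
  from the background orientation. Orientation identity is what counts, as
  the definition literally reads: an object element that happens to share
  the background orientation does not contribute. (The alternative
  provenance-based reading — object-derived vs background-filled — is noted
  but not used.)
* **Convexity**: region site count divided by the count of lattice sites
  inside the convex hull of the region's centers (hull membership includes
  the boundary; Delaunay-based point location). Degenerate regions (< 3
  sites or collinear) score 1 by convention. Counting in lattice sites
  keeps density and convexity in the same units.
* **Simplification**: 22.5°/67.5° → 45° and 112.5°/157.5° → 135° (nearest
  diagonal), reported with the fraction of elements changed; idempotent.

## Behavioral scoring

* **2AFC** (expert ranking): each session randomly partitions all candidate
  images into pairs (odd counts are an error; no bye rule exists). Wins are
  tallied per image; the retention rule keeps images with strictly more
  than the cut-off (default 9) wins — with 4 observers × 4 sessions every
  image appears in 16 comparisons, so 9/16 is eliminated and 10/16 kept.
* **Exclusions**: yes-rate is computed over answered (non-timeout) trials;
  participants are dropped when it exceeds 0.95 or falls below 0.05, or
  when they answered fewer than 80% of shown trials (all strict).
* **Recognizability**: yes/(yes+no) per image; timeouts are discarded,
  never scored.
* **Stability**: labels are mapped to 14 minor categories grouped into
  living, non-living/manipulable and non-living/non-manipulable. Refusals
  (empty labels) and unmapped labels are excluded from numerator and
  denominator; unmapped labels warn. The modal category is found at the
  *minor* level by default and stability is the modal fraction; the
  reported dominant category is that minor's major. This level choice is
  deliberate: scoring the published worked examples at the minor level
  reproduces both printed values exactly (3/7 = 0.43 with dominant animal →
  living; 5/6 = 0.83 with dominant object → non-living/manipulable),
  whereas major-level pooling would score the first example 4/7 because the
  food label joins living. `level="major"` is available. Ties break
  lexicographically and are flagged. Images never successfully named are
  reported as missing rather than zero, and a `few_namings` flag (default
  < 10 labels) marks images whose stability rests on few observations.
* **Final-set selection**: deterministic discards — more than 150 object
  elements, or more than 10% of elements changed by simplification, or
  recognizability below 0.5 with stability exactly 1.0. The published
  procedure's last step (retaining 78% of the remainder with a bias toward
  recognized-but-unstable images) is only partially specified, so it is
  exposed as a seedable stratified sampler (defaults 0.81 above / 0.75 at
  or below the recognition cut) rather than a fixed rule.
* The label→minor lexicon ships as an editable `CategoryMap` (YAML); the
  built-in table covers common labels and the test vocabulary, since no
  full lexicon is published.

## Synthetic data

`ShapeSpec` shapes (filled/outline rectangles, discs, rings, bars, crosses,
L-shapes, smoothed-noise blobs, multi-blob scatters) are drawn dark on
white inside the 336-px content area, each with a ground-truth pixel mask.
An optional interior texture (`texture_rms`) emulates photograph-like
objects whose interiors carry in-band structure; without it a filled shape
featurizes only along its contours, exactly as a line drawing would. The
shape set deliberately spans the metric space (convexity ≈ 1 down to ≈ 0.6,
density 1 down to outline-only). What the generator does *not* emulate:
natural image statistics, multi-object scenes, shading, or the semantic
content that makes real objects nameable — so passing tests demonstrate the
pipeline's mechanics and invariants, not recognition rates on real imagery.

`ObserverModel` simulates the norming tasks: per-image Bernoulli yes
probabilities, per-image label mixtures for yes trials, and optional
timeout/refusal rates. Simulated designs use the published protocol sizes
(4×4 sessions of 359 pairs for ranking; on the order of 120–159
participants seeing 100 of 217 images, i.e. ≈55–73 presentations per
image); parameter-recovery tests assert agreement within 4 standard errors
of the planted binomial quantities, on images with at least 10 labels.

## Numerical and design notes

* The published spatial-frequency band is taken in cycles/image (24–120);
  the cycles/degree figures sometimes quoted alongside are inconsistent
  with a 10° subtense and are ignored as device-dependent.
* Rendering uses no anti-aliasing; the exact-7-lit-pixels convention (rather
  than 7-px Euclidean length) is what makes luminance matching exact.
* Winner-take-all on an all-zero energy map yields an empty feature list
  (strict inequality against a zero threshold).
* Density/convexity are exactly invariant under the lattice's
  anisotropy-corrected quarter turn; under a true 90° rotation they are
  invariant only up to the 16/14 anisotropy of the lattice and the
  isotropic dilation kernel (property-tested with tolerance 0.1).
* All randomness flows through explicit `numpy.random.Generator` objects;
  the pipeline forks one master seed per image via `SeedSequence`, and
  reruns are byte-identical.
* Default problem sizes in the test suite (hundreds of rendered stimuli,
  217-image simulated norming runs, 20-fixture oracle sweeps) were chosen
  to exercise the full default grid while keeping the suite fast on a
  laptop.
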