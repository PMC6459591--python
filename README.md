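# faogen

Tools for building and norming **Fragmented Ambiguous Object (FAO)** stimuli:
line-segment images in which an embedded real-world object may or may not be
perceived, while low-level image properties — luminance, contrast, element
count, orientation statistics — are held exactly constant across the whole
stimulus set.

Stimuli of this kind let visual neuroscientists and psychophysicists study
object recognition, contour integration and figure/ground segmentation
without the confound that "object" and "non-object" images differ in the
features that drive early visual cortex. They are particularly suited to
work with clinical populations (psychosis, autism, aging), where low-level
and high-level visual changes must be disentangled.

## What it does

1. **Featurize** — a source image (line drawing or photograph) is scaled
   onto a 384×384 canvas, converted to grayscale by the unweighted RGB mean,
   and analyzed with an oriented band-pass filter bank (8 orientations
   0°–157.5° in 22.5° steps; 24–120 cycles/image, realized as
   frequency-domain log-Gabor quadrature filters). At each site of a
   hexagonal lattice (16 px horizontal / 14 px vertical spacing; 635 sites),
   a winner-take-all step assigns the orientation with the most power,
   producing a *feature list* for every location containing object content.
2. **QC** — candidates with fewer than 80 features, or whose 16-px-dilated
   segments split into more than 5 connected regions, are eliminated.
3. **Render** — every lattice site receives one 7-pixel segment: the feature
   orientation where the object is present, a randomly drawn background
   orientation elsewhere. Lines are 255 on a 128 background; every segment
   lights exactly 7 pixels, so all stimuli share the identical pixel-value
   histogram (luminance and contrast matching is exact by construction).
4. **Metrics** — orientation distribution, relative-orientation distribution
   between adjacent elements (collinear / parallel / acute / orthogonal /
   obtuse), object *density* (fraction of in-object lattice sites differing
   from the background orientation) and *convexity* (object area over
   convex-hull area, in lattice-site counts), plus the 8→4 orientation
   simplification.
5. **Behavior** — scoring of norming data: 2AFC win tallies and cut-offs,
   participant exclusion rules, per-image *recognizability*
   (yes / (yes + no) in a Yes/No task) and *stability* (fraction of naming
   labels in the image's modal semantic category, with a 14-minor /
   3-major category map), and the final-set selection filters.
6. **Synthetic fixtures** — parametric shapes with ground-truth masks and a
   simulated observer model, so the full pipeline is testable end to end
   without any image database or human data.

## Worked example

```python
import numpy as np
from faogen import (ShapeSpec, make_source_image, featurize, apply_qc,
                    choose_background, render_stimulus, compute_metrics)

img, _ = make_source_image(ShapeSpec(kind="disc", size=100, intensity=254.0,
                                     texture_rms=60.0, seed=4))
features = featurize(img)
report = apply_qc(features)
stimulus = render_stimulus(features, choose_background(np.random.default_rng(0)))
```

prints (see `examples/generate_stimuli.py`):

```
features: 115 of 635 grid locations
regions after dilation: 1
passes QC: True
background orientation: 135.0 deg
lit pixels: 4445 (= 635 segments x 7 pixels, identical for every stimulus)
```

The textured disc produced 115 object segments (well above the 80-feature
floor), its dilated segments form a single connected region, and the
rendered stimulus lights exactly 635 × 7 = 4445 pixels — the same count as
every other stimulus, which is what makes the set luminance- and
contrast-matched. `examples/` contains further narrative scripts for the
stimulus metrics, the 2AFC ranking stage, and norming-data scoring.

Scoring naming labels directly:

```python
from faogen import stability
score = stability(["whale", "stairs", "entryway", "whale", "fish",
                   "cucumber", "slide"])
# score.stability -> 0.4285…, score.dominant_major -> 'living'
```

A thin CLI mirrors the pipeline stages:
`faogen generate | qc | metrics | render | score | select | fixtures`.

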