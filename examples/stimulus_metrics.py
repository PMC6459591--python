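"""Compute the four stimulus statistics for a generated object.

Orientation and relative-orientation distributions summarize what early
visual cortex sees; density separates texture-defined from contour-defined
objects; convexity flags crescent-like shapes that bias figure/ground
judgments.
"""

from faogen import (ShapeSpec, compute_metrics, featurize, make_source_image,
                    simplify_orientations, visual_angle)

# a line-drawing-like shape: features follow the contours
img, _ = make_source_image(ShapeSpec(kind="L_shape", size=120, seed=2))
features = featurize(img)
metrics = compute_metrics(features, background_deg=45.0)

print(f"n_features: {metrics.n_features}")
print(f"density:    {metrics.density:.3f}  (1 = fully textured object)")
print(f"convexity:  {metrics.convexity:.3f}  (1 = convex footprint)")
print("orientation distribution:")
for theta, p in metrics.orientation_hist.items():
    print(f"  {theta:>5} deg: {p:.3f}")
print("relative orientations of adjacent elements:")
for cat, p in metrics.rel_orientation_hist.items():
    print(f"  {cat:>10}: {p:.3f}")

simplified, fraction_changed = simplify_orientations(features)
print(f"orientation simplification 8->4 changed {fraction_changed:.1%} "
      "of elements")
print(f"element size on screen: {visual_angle(7):.2f} deg; "
      f"spacing {visual_angle(16):.2f} deg")
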