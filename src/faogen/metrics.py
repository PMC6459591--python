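"""Stimulus statistics: orientation distributions, density, convexity.

Four statistics characterize each stimulus:

* the **orientation distribution** over all grid elements (object plus
  background fill);
* the **relative-orientation distribution** between immediately adjacent
  elements, classified into collinear / parallel / acute / orthogonal /
  obtuse — collinear pairs share an orientation that is also aligned with
  the direction joining their centers, so this statistic tracks contour
  content;
* **density** — of the grid locations inside the object's (possibly concave)
  perimeter, the fraction whose element orientation differs from the
  background orientation (1 = fully textured object, low values = an object
  defined only by its contours);
* **convexity** — the object region's area divided by the area of its convex
  hull, both counted in grid locations.

The object perimeter reuses the QC definition (segments dilated by the 16-px
square) with holes filled, so QC and metrics share a single notion of the
object's extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError

from .featurize import FeatureList
from .hexgrid import GridLocation, GridSpec, HexGrid
from .qc import QCConfig, dilated_object

__all__ = [
    "REL_CATEGORIES",
    "StimulusMetrics",
    "ViewingGeometry",
    "orientation_histogram",
    "classify_pair",
    "relative_orientation_histogram",
    "object_region",
    "density",
    "convexity",
    "simplify_orientations",
    "visual_angle",
    "compute_metrics",
]

REL_CATEGORIES = ("collinear", "parallel", "acute", "orthogonal", "obtuse")

_TOL = 1e-9


@dataclass(frozen=True)
class ViewingGeometry:
    """Maps pixels to visual angle (default: 10° total subtense at 384 px)."""

    subtense_deg: float = 10.0
    image_size_px: int = 384

    def __post_init__(self) -> None:
        if self.subtense_deg <= 0 or self.image_size_px <= 0:
            raise ValueError("viewing geometry parameters must be positive")


@dataclass
class StimulusMetrics:
    orientation_hist: dict[float, float]
    rel_orientation_hist: dict[str, float]
    density: float
    convexity: float
    n_features: int

    def to_dict(self) -> dict:
        out: dict = {"n_features": self.n_features,
                     "density": self.density, "convexity": self.convexity}
        out.update({f"p_orient_{k:g}": v for k, v in self.orientation_hist.items()})
        out.update({f"p_{k}": v for k, v in self.rel_orientation_hist.items()})
        return out


def _element_orientations(fl: FeatureList, grid: HexGrid,
                          background_deg: float) -> np.ndarray:
    return np.array(
        [fl.entries.get(loc, background_deg) for loc in grid.locations], dtype=float
    )


def orientation_histogram(
    fl: FeatureList,
    background_deg: float,
    orientations: tuple[float, ...] | None = None,
    grid: HexGrid | None = None,
) -> dict[float, float]:
    """Proportion of elements at each orientation, over the full grid."""
    grid = grid or HexGrid(fl.spec)
    thetas = _element_orientations(fl, grid, background_deg)
    if orientations is None:
        orientations = tuple(sorted(set(thetas) | {float(background_deg)}))
    counts = {o: 0 for o in orientations}
    for t in thetas:
        if t not in counts:
            raise ValueError(f"element orientation {t} not among {orientations}")
        counts[t] += 1
    n = len(thetas)
    return {o: c / n for o, c in counts.items()}


def _angdiff(a: float, b: float) -> float:
    """Minimal angular difference of two orientations, degrees in [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def classify_pair(theta_i: float, theta_j: float, direction_deg: float) -> str:
    """Classify one adjacent element pair.

    ``direction_deg`` is the orientation (mod 180°) of the line joining the
    two centers.  Same orientation aligned with that line (within 22.5°) is
    collinear, same orientation otherwise parallel; a 90° difference is
    orthogonal; an intermediate difference is acute when either element is
    aligned with the joining line (within 22.5°), otherwise obtuse.
    """
    delta = _angdiff(theta_i, theta_j)
    phi_i = _angdiff(theta_i, direction_deg)
    phi_j = _angdiff(theta_j, direction_deg)
    if delta <= _TOL:
        return "collinear" if min(phi_i, phi_j) <= 22.5 + _TOL else "parallel"
    if abs(delta - 90.0) <= _TOL:
        return "orthogonal"
    return "acute" if min(phi_i, phi_j) <= 22.5 + _TOL else "obtuse"


def relative_orientation_histogram(
    fl: FeatureList,
    background_deg: float,
    grid: HexGrid | None = None,
) -> dict[str, float]:
    """Distribution over the five pairwise categories for all adjacent pairs."""
    grid = grid or HexGrid(fl.spec)
    thetas = _element_orientations(fl, grid, background_deg)
    centers = grid.centers
    counts = dict.fromkeys(REL_CATEGORIES, 0)
    pairs = grid.adjacent_pairs()
    for i, j in pairs:
        dx = centers[j, 0] - centers[i, 0]
        dy = centers[j, 1] - centers[i, 1]
        # y grows downward; orientation angles are counterclockwise in
        # standard view, hence the sign flip.
        direction = np.degrees(np.arctan2(-dy, dx)) % 180.0
        counts[classify_pair(thetas[i], thetas[j], direction)] += 1
    n = len(pairs)
    return {k: c / n for k, c in counts.items()}


def object_region(
    fl: FeatureList,
    spec: GridSpec | None = None,
    cfg: QCConfig | None = None,
    grid: HexGrid | None = None,
) -> list[GridLocation]:
    """Grid locations inside the object's perimeter.

    The perimeter is the hole-filled QC dilation of the object's segments;
    the region is every grid location whose center falls inside it.  Always a
    superset of the feature list's own locations.
    """
    spec = spec or fl.spec
    grid = grid or HexGrid(spec)
    dil = dilated_object(fl, spec, cfg)
    if not dil.any():
        return []
    filled = ndimage.binary_fill_holes(dil)
    return [loc for loc in grid.locations if filled[loc.y_px, loc.x_px]]


def density(
    fl: FeatureList,
    background_deg: float,
    spec: GridSpec | None = None,
    cfg: QCConfig | None = None,
    region: list[GridLocation] | None = None,
) -> float:
    """Fraction of in-object grid locations differing from the background.

    Orientation identity is what counts: an object element that happens to
    share the background orientation does not contribute.
    """
    if region is None:
        region = object_region(fl, spec, cfg)
    if not region:
        raise ValueError("object region is empty; cannot compute density")
    differing = sum(
        1
        for loc in region
        if loc in fl.entries and _angdiff(fl.entries[loc], background_deg) > _TOL
    )
    return differing / len(region)


def convexity(
    region: list[GridLocation],
    grid: HexGrid | None = None,
) -> float:
    """Region area over convex-hull area, both in grid-location counts.

    Equals 1 for convex regions; degenerate (collinear or < 3 point) regions
    score 1 by convention.
    """
    if grid is None:
        raise ValueError("convexity requires the grid the region lives on")
    if len(region) < 3:
        return 1.0
    pts = np.array([(l.x_px, l.y_px) for l in region], dtype=float)
    try:
        tri = Delaunay(pts)
    except QhullError:
        return 1.0  # collinear region: hull has no area
    inside = tri.find_simplex(grid.centers) >= 0
    hull_count = int(inside.sum())
    return len(region) / hull_count


def simplify_orientations(fl: FeatureList) -> tuple[FeatureList, float]:
    """Replace the rare off-axis orientations with the nearest diagonal.

    22.5° and 67.5° become 45°; 112.5° and 157.5° become 135°.  Returns the
    simplified feature list (only 0/45/90/135 remain) and the fraction of
    entries changed.  Idempotent; never changes the feature count.
    """
    mapping = {22.5: 45.0, 67.5: 45.0, 112.5: 135.0, 157.5: 135.0}
    changed = 0
    entries = {}
    for loc, theta in fl.entries.items():
        new = mapping.get(float(theta), float(theta))
        if new != theta:
            changed += 1
        entries[loc] = new
    frac = changed / fl.n_features if fl.n_features else 0.0
    return FeatureList(fl.spec, entries), frac


def visual_angle(extent_px: float, geom: ViewingGeometry | None = None) -> float:
    """Visual angle in degrees subtended by ``extent_px`` pixels."""
    geom = geom or ViewingGeometry()
    if extent_px < 0:
        raise ValueError("extent_px must be nonnegative")
    return extent_px * geom.subtense_deg / geom.image_size_px


def compute_metrics(
    fl: FeatureList,
    background_deg: float,
    spec: GridSpec | None = None,
    orientations: tuple[float, ...] | None = None,
    cfg: QCConfig | None = None,
) -> StimulusMetrics:
    """All four statistics for one stimulus."""
    spec = spec or fl.spec
    grid = HexGrid(spec)
    region = object_region(fl, spec, cfg, grid)
    return StimulusMetrics(
        orientation_hist=orientation_histogram(fl, background_deg, orientations, grid),
        rel_orientation_hist=relative_orientation_histogram(fl, background_deg, grid),
        density=density(fl, background_deg, spec, cfg, region),
        convexity=convexity(region, grid),
        n_features=fl.n_features,
    )
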