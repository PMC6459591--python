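"""Synthetic source images and simulated behavioral data.

Everything downstream of the image databases is testable without any
download: parametric shapes (rectangles, discs, rings, bars, crosses,
L-shapes, smoothed random blobs and multi-blob scatters) stand in for the
source photographs and line drawings, and a simple observer model generates
Yes/No, naming and 2AFC tables with known ground truth.

Shapes are dark objects on a white background, drawn inside the 336-px
content area of the default canvas, mirroring the scale of preprocessed
database images.  The shape kinds deliberately span the metric space:
convexity near 1 (filled rectangle, disc) down to well below 1 (L-shape,
ring), density 1 (filled) down to outline-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .behavior import pair_schedule
from .featurize import FeatureList, OrientationBank
from .hexgrid import GridSpec, HexGrid

__all__ = [
    "ShapeSpec",
    "ObserverModel",
    "make_source_image",
    "random_feature_list",
    "simulate_responses",
    "simulate_2afc",
]

SHAPE_KINDS = (
    "filled_rect",
    "outline_rect",
    "disc",
    "ring",
    "bar",
    "cross",
    "L_shape",
    "random_blob",
    "multi_blob",
)

OBJECT_VALUE = 30.0
BACKGROUND_VALUE = 255.0


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric synthetic object.

    ``size`` is the characteristic half-extent in pixels; ``position`` the
    center in canvas coordinates (default: canvas center); ``k`` the number
    of blobs for ``multi_blob``; ``min_separation`` the guaranteed pairwise
    center distance between blobs.
    """

    kind: str = "disc"
    size: int = 80
    position: tuple[int, int] | None = None
    intensity: float = OBJECT_VALUE
    rotation_deg: float = 0.0
    outline_px: int = 6
    k: int = 2
    min_separation: int = 60
    texture_rms: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.size < 2:
            raise ValueError("size must be >= 2")


def _coords(n: int, center: tuple[int, int]):
    yy, xx = np.mgrid[0:n, 0:n]
    return xx - center[0], yy - center[1]


def _rotate(xx, yy, deg: float):
    t = np.deg2rad(deg)
    # standard-view counterclockwise rotation in y-down raster coordinates
    return xx * np.cos(t) - yy * np.sin(t), xx * np.sin(t) + yy * np.cos(t)


def make_source_image(
    shape: ShapeSpec,
    spec: GridSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a shape; returns (image, ground-truth object mask).

    The image is grayscale in [0, 255] at canvas size with a white
    background; the mask marks exactly the drawn object pixels.
    Deterministic given the shape spec (its ``seed`` drives the random
    kinds).
    """
    spec = spec or GridSpec()
    n = spec.image_size_px
    center = shape.position or (n // 2, n // 2)
    rng = np.random.default_rng(shape.seed)
    s = shape.size
    xx, yy = _coords(n, center)
    if shape.rotation_deg:
        xx, yy = _rotate(xx, yy, -shape.rotation_deg)

    if shape.kind == "filled_rect":
        mask = (np.abs(xx) <= s) & (np.abs(yy) <= s)
    elif shape.kind == "outline_rect":
        outer = (np.abs(xx) <= s) & (np.abs(yy) <= s)
        w = shape.outline_px
        inner = (np.abs(xx) <= s - w) & (np.abs(yy) <= s - w)
        mask = outer & ~inner
    elif shape.kind == "disc":
        mask = xx**2 + yy**2 <= s**2
    elif shape.kind == "ring":
        r2 = xx**2 + yy**2
        mask = (r2 <= s**2) & (r2 >= (s - shape.outline_px) ** 2)
    elif shape.kind == "bar":
        mask = (np.abs(xx) <= s) & (np.abs(yy) <= max(2, s // 8))
    elif shape.kind == "cross":
        arm = max(2, s // 4)
        mask = ((np.abs(xx) <= s) & (np.abs(yy) <= arm)) | (
            (np.abs(yy) <= s) & (np.abs(xx) <= arm)
        )
    elif shape.kind == "L_shape":
        arm = max(3, s // 3)
        mask = ((np.abs(xx) <= arm) & (np.abs(yy) <= s)) | (
            (np.abs(yy - (s - arm)) <= arm) & (xx >= 0) & (xx <= 2 * s)
        )
    elif shape.kind == "random_blob":
        noise = rng.normal(size=(n, n))
        smooth = ndimage.gaussian_filter(noise, sigma=s / 3)
        mask = smooth > np.percentile(smooth, 92)
        # keep the blob nearest the requested center
        labels, count = ndimage.label(mask)
        if count > 1:
            centers = ndimage.center_of_mass(mask, labels, range(1, count + 1))
            d = [np.hypot(cy - center[1], cx - center[0]) for cy, cx in centers]
            mask = labels == (int(np.argmin(d)) + 1)
    elif shape.kind == "multi_blob":
        mask = np.zeros((n, n), dtype=bool)
        centers: list[tuple[int, int]] = []
        margin = n // 8
        radius = max(8, min(s, (shape.min_separation - 4) // 2))
        while len(centers) < shape.k:
            cx = int(rng.integers(margin, n - margin))
            cy = int(rng.integers(margin, n - margin))
            if all(
                np.hypot(cx - ox, cy - oy) >= shape.min_separation + 2 * radius
                for ox, oy in centers
            ):
                centers.append((cx, cy))
        for cx, cy in centers:
            bx, by = _coords(n, (cx, cy))
            mask |= bx**2 + by**2 <= radius**2
    else:  # pragma: no cover - guarded by ShapeSpec
        raise ValueError(shape.kind)

    img = np.full((n, n), BACKGROUND_VALUE)
    img[mask] = shape.intensity
    if shape.texture_rms > 0:
        # Photograph-like interior texture: without it a uniform fill only
        # produces features along its contour, as a line drawing would.
        noise = rng.normal(0.0, shape.texture_rms, size=(n, n))
        img[mask] += noise[mask]
        img = np.clip(img, 0.0, 255.0)
    return img, mask


def random_feature_list(
    grid: HexGrid,
    n_features: int,
    rng: np.random.Generator,
    bank: OrientationBank | None = None,
    clustered: bool = True,
) -> FeatureList:
    """Plant a feature list with known orientations at random locations.

    With ``clustered`` (default) the locations grow as a connected patch from
    a random seed site, mimicking a real object's footprint; otherwise they
    are sampled uniformly over the grid.
    """
    bank = bank or OrientationBank()
    if n_features > len(grid):
        raise ValueError("more features requested than grid locations")
    if clustered:
        start = int(rng.integers(len(grid)))
        chosen = {start}
        frontier = set(grid._adjacency[start])
        while len(chosen) < n_features:
            if not frontier:  # disconnected leftover; jump
                frontier = set(range(len(grid))) - chosen
            pick = int(rng.choice(sorted(frontier)))
            chosen.add(pick)
            frontier |= grid._adjacency[pick]
            frontier -= chosen
        idx = sorted(chosen)
    else:
        idx = sorted(rng.choice(len(grid), size=n_features, replace=False))
    thetas = rng.choice(bank.orientations_deg, size=len(idx))
    entries = {grid.locations[i]: float(t) for i, t in zip(idx, thetas)}
    return FeatureList(grid.spec, entries)


# ---------------------------------------------------------------------------
# behavioral simulation


@dataclass
class ObserverModel:
    """Generative model for Yes/No + Naming responses.

    ``p_yes`` maps image id -> probability of a yes response;
    ``label_distribution`` maps image id -> (labels, probabilities) used when
    the observer says yes; ``timeout_rate`` is the chance a trial times out
    (discarded when scoring); ``refusal_rate`` the chance a yes trial is
    followed by a naming refusal (empty label).
    """

    p_yes: dict
    label_distribution: dict = field(default_factory=dict)
    timeout_rate: float = 0.0
    refusal_rate: float = 0.0

    def __post_init__(self) -> None:
        for img, p in self.p_yes.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_yes[{img!r}] outside [0, 1]")
        for img, (labels, probs) in self.label_distribution.items():
            probs = np.asarray(probs, dtype=float)
            if len(labels) != len(probs) or not np.isclose(probs.sum(), 1.0):
                raise ValueError(f"label distribution for {img!r} not normalized")


def simulate_responses(
    image_ids,
    model: ObserverModel,
    n_participants: int,
    images_per_participant: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the Yes/No and Naming tables.

    Each participant sees a random subset of the images; yes responses are
    Bernoulli draws from the planted per-image probability, and each yes
    trial yields a label drawn from the planted label distribution (or a
    refusal).  Naming records exist only for yes trials, matching the task
    structure.
    """
    image_ids = list(image_ids)
    if images_per_participant > len(image_ids):
        raise ValueError("images_per_participant exceeds the number of images")
    yes_rows, name_rows = [], []
    for p in range(n_participants):
        pid = f"p{p:03d}"
        shown = rng.choice(len(image_ids), size=images_per_participant, replace=False)
        for i in shown:
            img = image_ids[i]
            if model.timeout_rate and rng.random() < model.timeout_rate:
                yes_rows.append({"participant": pid, "image": img, "response": "timeout"})
                continue
            said_yes = rng.random() < model.p_yes[img]
            yes_rows.append(
                {"participant": pid, "image": img,
                 "response": "yes" if said_yes else "no"}
            )
            if said_yes:
                if model.refusal_rate and rng.random() < model.refusal_rate:
                    label = ""
                else:
                    labels, probs = model.label_distribution[img]
                    label = str(rng.choice(labels, p=probs))
                name_rows.append({"participant": pid, "image": img, "label": label})
    yesno = pd.DataFrame(yes_rows, columns=["participant", "image", "response"])
    naming = pd.DataFrame(name_rows, columns=["participant", "image", "label"])
    return yesno, naming


def simulate_2afc(
    image_ids,
    strengths: dict,
    n_observers: int,
    n_sessions: int,
    rng: np.random.Generator,
    deterministic: bool = False,
) -> pd.DataFrame:
    """Simulate the expert 2AFC ranking task.

    Every observer completes ``n_sessions`` sessions; each session pairs all
    images once.  The winner of a pair is the higher-strength image, either
    deterministically or by a Bradley-Terry draw with probability
    s_a / (s_a + s_b).
    """
    rows = []
    for o in range(n_observers):
        for s in range(n_sessions):
            for a, b in pair_schedule(image_ids, rng):
                sa, sb = strengths[a], strengths[b]
                if deterministic:
                    chosen = a if sa >= sb else b
                else:
                    chosen = a if rng.random() < sa / (sa + sb) else b
                rows.append(
                    {"observer": f"o{o}", "session": s,
                     "image_a": a, "image_b": b, "chosen": chosen}
                )
    return pd.DataFrame(rows)
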