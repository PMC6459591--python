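"""Render feature lists into two-valued line-segment stimuli.

Every grid location carries exactly one segment: the feature-list orientation
where the object is present, the (randomly drawn) background orientation
everywhere else.  A segment lights exactly ``segment_len_px`` pixels whatever
its orientation, so every stimulus generated under one grid spec has the same
lit-pixel count — luminance and contrast matching hold exactly by
construction.  Lines are drawn at value 255 on a 128 background; there is no
anti-aliasing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from PIL import Image

from .featurize import FeatureList, OrientationBank
from .hexgrid import GridSpec, HexGrid

__all__ = ["StimulusImage", "choose_background", "segment_offsets", "render_stimulus"]

LINE_VALUE = 255
BACKGROUND_VALUE = 128


@dataclass
class StimulusImage:
    """A rendered stimulus: pixel array plus its provenance."""

    pixels: np.ndarray
    background_deg: float
    features: FeatureList
    rng_seed: int | None = None

    @property
    def lit_count(self) -> int:
        return int(np.sum(self.pixels == LINE_VALUE))

    def save(self, path: str | Path, sidecar: bool = True) -> None:
        """Write a lossless 8-bit grayscale PNG plus a provenance sidecar."""
        path = Path(path)
        Image.fromarray(self.pixels, mode="L").save(path, format="PNG")
        if sidecar:
            meta = {
                "background_deg": self.background_deg,
                "rng_seed": self.rng_seed,
                "n_features": self.features.n_features,
            }
            path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def choose_background(rng: np.random.Generator, bank: OrientationBank | None = None) -> float:
    """Draw the background orientation uniformly from the bank's orientations."""
    bank = bank or OrientationBank()
    return float(rng.choice(bank.orientations_deg))


@lru_cache(maxsize=64)
def segment_offsets(orientation_deg: float, segment_len_px: int = 7) -> tuple[tuple[int, int], ...]:
    """Pixel offsets (dx, dy) of a segment centered at the origin.

    Steps run along the orientation direction (y-down raster: dy = -sin),
    rounded to the nearest pixel; the construction yields exactly
    ``segment_len_px`` distinct pixels for every orientation in the bank.
    """
    half = segment_len_px // 2
    t = np.deg2rad(orientation_deg)
    c, s = np.cos(t), np.sin(t)
    ks = np.arange(-half, half + 1)
    # Bresenham-style run: unit steps along the dominant axis, the other
    # axis rounded — one pixel per step, so the count is exact for every
    # orientation.
    if abs(c) >= abs(s):
        dx = ks
        dy = np.rint(-ks * s / c).astype(int) if c != 0 else np.zeros_like(ks)
    else:
        dy = -ks
        dx = np.rint(ks * c / s).astype(int)
    offsets = tuple(sorted(zip(dx.tolist(), dy.tolist())))
    if len(set(offsets)) != segment_len_px:
        raise ValueError(
            f"orientation {orientation_deg} does not rasterize to "
            f"{segment_len_px} distinct pixels"
        )
    return offsets


def render_stimulus(
    fl: FeatureList,
    background_deg: float,
    spec: GridSpec | None = None,
    rng_seed: int | None = None,
) -> StimulusImage:
    """Place one segment at every grid location and return the stimulus.

    Pure function of (features, background, spec): rendering twice gives the
    identical pixel array.
    """
    spec = spec or fl.spec
    grid = HexGrid(spec)
    for loc in fl.entries:
        if loc not in grid:
            raise ValueError(f"feature location {loc} is off the grid")
    img = np.full(
        (spec.image_size_px, spec.image_size_px), BACKGROUND_VALUE, dtype=np.uint8
    )
    for loc in grid:
        theta = fl.entries.get(loc, background_deg)
        for dx, dy in segment_offsets(float(theta), spec.segment_len_px):
            img[loc.y_px + dy, loc.x_px + dx] = LINE_VALUE
    return StimulusImage(img, float(background_deg), fl, rng_seed)
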