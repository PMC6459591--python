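"""Automatic elimination rules for candidate feature lists.

Two filters decide whether a candidate survives:

* **count filter** — a feature list with fewer than 80 of the 635 possible
  segments carries too little object to be useful;
* **disjointedness filter** — the object segments (background excluded) are
  dilated with a 16x16-pixel square and the dilated blob is labeled into
  connected regions; more than 5 regions means the gridding shattered the
  object and the candidate is dropped.

Both boundaries are strict: 80 features passes, 5 regions passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .featurize import FeatureList
from .hexgrid import GridSpec
from .render import segment_offsets

__all__ = ["QCConfig", "QCReport", "object_mask", "count_filter",
           "region_count", "disjointedness_filter", "apply_qc"]


@dataclass(frozen=True)
class QCConfig:
    min_features: int = 80
    max_regions: int = 5
    blur_kernel_px: int = 16

    def __post_init__(self) -> None:
        if min(self.min_features, self.max_regions, self.blur_kernel_px) < 1:
            raise ValueError("QC parameters must be positive")


@dataclass(frozen=True)
class QCReport:
    n_features: int
    n_regions: int
    passes_count: bool
    passes_disjointedness: bool

    @property
    def passed(self) -> bool:
        return self.passes_count and self.passes_disjointedness


def object_mask(fl: FeatureList, spec: GridSpec | None = None) -> np.ndarray:
    """Boolean image of the object's segment pixels only (no background)."""
    spec = spec or fl.spec
    mask = np.zeros((spec.image_size_px, spec.image_size_px), dtype=bool)
    for loc, theta in fl.entries.items():
        for dx, dy in segment_offsets(float(theta), spec.segment_len_px):
            mask[loc.y_px + dy, loc.x_px + dx] = True
    return mask


def count_filter(fl: FeatureList, cfg: QCConfig | None = None) -> tuple[bool, int]:
    """Pass/fail on the minimum-feature rule; returns (passed, n_features)."""
    cfg = cfg or QCConfig()
    n = fl.n_features
    return n >= cfg.min_features, n


def dilated_object(fl: FeatureList, spec: GridSpec | None = None,
                   cfg: QCConfig | None = None) -> np.ndarray:
    """Object mask dilated by the square blur kernel (thresholded > 0)."""
    cfg = cfg or QCConfig()
    k = cfg.blur_kernel_px
    mask = object_mask(fl, spec)
    if not mask.any():
        return mask
    return ndimage.binary_dilation(mask, structure=np.ones((k, k), dtype=bool))


def region_count(fl: FeatureList, spec: GridSpec | None = None,
                 cfg: QCConfig | None = None) -> int:
    """Number of 8-connected regions in the dilated object image."""
    dil = dilated_object(fl, spec, cfg)
    if not dil.any():
        return 0
    _, n = ndimage.label(dil, structure=np.ones((3, 3), dtype=bool))
    return int(n)


def disjointedness_filter(fl: FeatureList, spec: GridSpec | None = None,
                          cfg: QCConfig | None = None) -> tuple[bool, int]:
    """Pass/fail on the disjointedness rule; returns (passed, n_regions)."""
    cfg = cfg or QCConfig()
    n = region_count(fl, spec, cfg)
    return n <= cfg.max_regions, n


def apply_qc(fl: FeatureList, spec: GridSpec | None = None,
             cfg: QCConfig | None = None) -> QCReport:
    cfg = cfg or QCConfig()
    ok_count, n_feat = count_filter(fl, cfg)
    ok_disj, n_reg = disjointedness_filter(fl, spec, cfg)
    return QCReport(n_feat, n_reg, ok_count, ok_disj)
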