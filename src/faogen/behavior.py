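"""Scoring of behavioral norming data.

Three tasks norm the stimulus set:

* a spatial **2AFC** in which expert observers pick, from two candidate
  stimuli, the one that "looks more like a single object"; images are ranked
  by win count and the top of the ranking is carried forward;
* a **Yes/No** task ("Does this image contain a known object?") from which
  each image's *recognizability* is the proportion of yes responses among
  answered (non-timeout) trials, after excluding careless or low-acuity-style
  response patterns;
* a **Naming** task in which every image a participant endorsed is labeled;
  labels are mapped to 14 minor semantic categories grouped into 3 major
  categories (living; non-living/manipulable; non-living/non-manipulable),
  and an image's *stability* is the fraction of its labels falling in its
  modal category.

Stability is scored at the minor-category level by default (the modal minor
category is found, and the reported dominant category is that minor's major);
``level="major"`` pools the labels into the three major categories first.
The minor-level rule reproduces the published worked examples exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CategoryMap",
    "ExclusionConfig",
    "SelectionConfig",
    "StabilityScore",
    "pair_schedule",
    "tally_wins",
    "select_top_third",
    "exclude_participants",
    "recognizability",
    "stability",
    "stability_table",
    "select_final_set",
]

MAJOR_CATEGORIES = ("living", "non-living/manipulable", "non-living/non-manipulable")

DEFAULT_MAJOR_OF = {
    "human": "living",
    "animal": "living",
    "humanoid": "living",
    "instrument": "living",
    "food": "living",
    "plant": "living",
    "object": "non-living/manipulable",
    "weapon": "non-living/manipulable",
    "body part": "non-living/manipulable",
    "furniture": "non-living/manipulable",
    "building": "non-living/non-manipulable",
    "place": "non-living/non-manipulable",
    "vehicle": "non-living/non-manipulable",
    "weather": "non-living/non-manipulable",
}

# Label lexicon: free-text label -> minor category.  Deliberately small; real
# deployments extend it (CategoryMap.from_yaml) with the labels their
# participants actually produce.
DEFAULT_MINOR_OF = {
    "whale": "animal",
    "fish": "animal",
    "goldfish": "animal",
    "cat": "animal",
    "dog": "animal",
    "bird": "animal",
    "person": "human",
    "man": "human",
    "woman": "human",
    "face": "human",
    "robot": "humanoid",
    "guitar": "instrument",
    "violin": "instrument",
    "cucumber": "food",
    "apple": "food",
    "banana": "food",
    "tree": "plant",
    "flower": "plant",
    "stairs": "object",
    "slide": "object",
    "tennis racket": "object",
    "key": "object",
    "club": "object",
    "hammer": "object",
    "umbrella": "object",
    "chair": "furniture",
    "table": "furniture",
    "bed": "furniture",
    "sword": "weapon",
    "gun": "weapon",
    "hand": "body part",
    "foot": "body part",
    "leg": "body part",
    "house": "building",
    "church": "building",
    "entryway": "place",
    "bridge": "place",
    "mountain": "place",
    "car": "vehicle",
    "airplane": "vehicle",
    "boat": "vehicle",
    "bicycle": "vehicle",
    "cloud": "weather",
    "lightning": "weather",
}


@dataclass
class CategoryMap:
    """Label → minor category → major category lookup."""

    minor_of: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MINOR_OF))
    major_of: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MAJOR_OF))

    def minor(self, label: str) -> str | None:
        return self.minor_of.get(label.strip().lower())

    def major(self, label: str) -> str | None:
        m = self.minor(label)
        return self.major_of.get(m) if m is not None else None

    def to_yaml(self, path=None) -> str | None:
        text = yaml.safe_dump({"minor_of": self.minor_of, "major_of": self.major_of})
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, path) -> "CategoryMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(minor_of=doc["minor_of"], major_of=doc["major_of"])


@dataclass(frozen=True)
class ExclusionConfig:
    """Participant exclusion thresholds (strict comparisons)."""

    max_yes_rate: float = 0.95
    min_yes_rate: float = 0.05
    min_response_rate: float = 0.80


@dataclass(frozen=True)
class SelectionConfig:
    """Final-set selection rules."""

    max_object_elements: int = 150
    max_adjusted_fraction: float = 0.10
    low_recognition_cut: float = 0.5
    full_stability: float = 1.0
    retain_fraction_high: float = 0.81
    retain_fraction_low: float = 0.75


# ---------------------------------------------------------------------------
# Stage 2: 2AFC


def pair_schedule(image_ids, rng: np.random.Generator) -> list[tuple]:
    """Random partition of the images into unordered pairs (one session).

    Each image appears in exactly one of the n/2 pairs; an odd image count is
    an error.
    """
    ids = list(image_ids)
    if len(ids) % 2 != 0:
        raise ValueError(f"cannot pair an odd number of images ({len(ids)})")
    order = rng.permutation(len(ids))
    return [(ids[order[k]], ids[order[k + 1]]) for k in range(0, len(ids), 2)]


def tally_wins(records: pd.DataFrame) -> pd.DataFrame:
    """Win and exposure counts per image from 2AFC trial records.

    ``records`` needs columns image_a, image_b, chosen; every trial produces
    exactly one win, so wins sum to the number of records.
    """
    bad = ~(records["chosen"].eq(records["image_a"])
            | records["chosen"].eq(records["image_b"]))
    if bad.any():
        raise ValueError(f"chosen image not in pair at rows {list(records.index[bad])}")
    exposures = pd.concat([records["image_a"], records["image_b"]]).value_counts()
    wins = records["chosen"].value_counts()
    out = pd.DataFrame({"exposures": exposures})
    out["wins"] = wins.reindex(out.index).fillna(0).astype(int)
    out.index.name = "image"
    return out.sort_index()


def select_top_third(tally: pd.DataFrame, cutoff: int = 9) -> list:
    """Images retained by the win-count rule: strictly more than ``cutoff``
    wins survive (9 of 16 is eliminated, 10 retained)."""
    keep = tally.index[tally["wins"] > cutoff]
    return sorted(keep)


# ---------------------------------------------------------------------------
# Stage 3: Yes/No and Naming

_VALID_RESPONSES = {"yes", "no", "timeout"}


def _check_responses(yesno: pd.DataFrame) -> None:
    bad = ~yesno["response"].isin(_VALID_RESPONSES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"invalid response token {yesno['response'].iloc[row]!r} at row {row}"
        )


def exclude_participants(
    yesno: pd.DataFrame, cfg: ExclusionConfig | None = None
) -> tuple[list, pd.DataFrame]:
    """Apply the careless-responding and completion exclusions.

    Yes-rate is computed over answered (non-timeout) trials; response rate is
    answered/shown.  Participants are dropped when yes-rate exceeds 0.95, is
    below 0.05, or response rate is below 0.80 (all strict).  Returns the
    retained participant ids and a per-participant summary table.
    """
    cfg = cfg or ExclusionConfig()
    _check_responses(yesno)
    rows = []
    for pid, sub in yesno.groupby("participant"):
        shown = len(sub)
        answered = int((sub["response"] != "timeout").sum())
        n_yes = int((sub["response"] == "yes").sum())
        yes_rate = n_yes / answered if answered else 0.0
        response_rate = answered / shown
        excluded = (
            yes_rate > cfg.max_yes_rate
            or yes_rate < cfg.min_yes_rate
            or response_rate < cfg.min_response_rate
        )
        rows.append(
            {"participant": pid, "shown": shown, "answered": answered,
             "yes_rate": yes_rate, "response_rate": response_rate,
             "excluded": excluded}
        )
    table = pd.DataFrame(rows).set_index("participant")
    retained = sorted(table.index[~table["excluded"]])
    return retained, table


def recognizability(yesno: pd.DataFrame, image_id=None) -> pd.Series | float:
    """Per-image proportion of yes among answered responses.

    Timeout trials are discarded and never scored.  With ``image_id`` given,
    returns that image's rate; otherwise a Series over all images.
    """
    _check_responses(yesno)
    answered = yesno[yesno["response"] != "timeout"]
    rate = answered.groupby("image")["response"].agg(lambda s: (s == "yes").mean())
    rate.name = "recognizability"
    if image_id is not None:
        return float(rate.loc[image_id])
    return rate


@dataclass(frozen=True)
class StabilityScore:
    stability: float
    dominant_major: str
    dominant_minor: str | None
    n_labels: int
    tie: bool


def stability(
    labels,
    cmap: CategoryMap | None = None,
    level: str = "minor",
) -> StabilityScore | None:
    """Semantic stability of one image's label set.

    Refusals (empty labels) and unmapped labels are excluded from both the
    numerator and the denominator; an unmapped label additionally triggers a
    warning.  Returns ``None`` when no scorable label remains (an image
    consistently rejected at naming time).  Ties between equally modal
    categories break lexicographically and set the ``tie`` flag.
    """
    if level not in ("minor", "major"):
        raise ValueError("level must be 'minor' or 'major'")
    cmap = cmap or CategoryMap()
    cats = []
    for lab in labels:
        lab = (lab or "").strip()
        if not lab:
            continue  # refusal
        minor = cmap.minor(lab)
        if minor is None:
            warnings.warn(f"label {lab!r} has no category assignment; skipped")
            continue
        cats.append(minor if level == "minor" else cmap.major_of[minor])
    if not cats:
        return None
    counts = pd.Series(cats).value_counts()
    top = counts.max()
    modal = sorted(counts.index[counts == top])
    dominant = modal[0]
    if level == "minor":
        dom_minor, dom_major = dominant, cmap.major_of[dominant]
    else:
        dom_minor, dom_major = None, dominant
    return StabilityScore(
        stability=top / len(cats),
        dominant_major=dom_major,
        dominant_minor=dom_minor,
        n_labels=len(cats),
        tie=len(modal) > 1,
    )


def stability_table(
    naming: pd.DataFrame,
    cmap: CategoryMap | None = None,
    level: str = "minor",
    min_namings: int = 10,
) -> pd.DataFrame:
    """Per-image stability from a naming table (columns participant, image,
    label).  Images with no scorable label get NaN; a ``few_namings`` flag
    marks images named fewer than ``min_namings`` times."""
    cmap = cmap or CategoryMap()
    rows = []
    for img, sub in naming.groupby("image"):
        score = stability(sub["label"].tolist(), cmap, level)
        if score is None:
            rows.append({"image": img, "stability": np.nan, "dominant_major": None,
                         "n_labels": 0, "tie": False, "few_namings": True})
        else:
            rows.append({"image": img, "stability": score.stability,
                         "dominant_major": score.dominant_major,
                         "n_labels": score.n_labels, "tie": score.tie,
                         "few_namings": score.n_labels < min_namings})
    return pd.DataFrame(rows).set_index("image").sort_index()


# ---------------------------------------------------------------------------
# Final-set selection


def select_final_set(
    table: pd.DataFrame,
    cfg: SelectionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Apply the final-set selection rules to a per-image table.

    ``table`` needs columns n_features, adjusted_fraction, recognizability,
    stability.  Two deterministic discards apply: (1) more than
    ``max_object_elements`` object elements or more than
    ``max_adjusted_fraction`` of elements changed by orientation
    simplification; (2) rarely recognized (below ``low_recognition_cut``) but
    perfectly stable images.  When ``rng`` is given, a third, stratified
    retention step keeps ``retain_fraction_high`` of images above the
    recognition cut and ``retain_fraction_low`` of the rest (the published
    procedure describes this step only as a biased subsampling, so it is
    exposed as a seedable sampler rather than a fixed rule).
    """
    cfg = cfg or SelectionConfig()
    t = table.copy()
    rule1 = (t["n_features"] > cfg.max_object_elements) | (
        t["adjusted_fraction"] > cfg.max_adjusted_fraction
    )
    rule2 = (t["recognizability"] < cfg.low_recognition_cut) & (
        t["stability"] == cfg.full_stability
    )
    t = t[~rule1 & ~rule2]
    if rng is not None:
        high = t.index[t["recognizability"] > cfg.low_recognition_cut]
        low = t.index[t["recognizability"] <= cfg.low_recognition_cut]
        keep_high = rng.choice(
            high, size=round(cfg.retain_fraction_high * len(high)), replace=False
        )
        keep_low = rng.choice(
            low, size=round(cfg.retain_fraction_low * len(low)), replace=False
        )
        t = t.loc[sorted([*keep_high, *keep_low])]
    return t
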