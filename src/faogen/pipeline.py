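"""End-to-end stimulus generation: preprocess → featurize → QC → render → metrics.

A :class:`PipelineConfig` collects every tunable (grid geometry, filter bank,
QC thresholds, behavioral exclusion/selection rules, viewing geometry, master
seed) and round-trips losslessly through YAML.  ``run_pipeline`` drives a
batch of source images through the full chain, writing PNG stimuli with
provenance sidecars, feature-list JSONs, and QC/metrics CSV reports.

One master seed is forked deterministically per image (for the background
orientation draw), so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import ExclusionConfig, SelectionConfig
from .featurize import FeatureList, OrientationBank, featurize, preprocess
from .hexgrid import GridSpec, HexGrid
from .metrics import ViewingGeometry, compute_metrics
from .qc import QCConfig, apply_qc
from .render import choose_background, render_stimulus

__all__ = ["PipelineConfig", "run_pipeline", "read_response_table"]

log = logging.getLogger("faogen")


@dataclass
class PipelineConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    bank: OrientationBank = field(default_factory=OrientationBank)
    qc: QCConfig = field(default_factory=QCConfig)
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    viewing: ViewingGeometry = field(default_factory=ViewingGeometry)
    objectness_threshold: float = 0.1
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bank"]["orientations_deg"] = list(self.bank.orientations_deg)
        return d

    def to_yaml(self, path=None) -> str | None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is None:
            return text
        Path(path).write_text(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        d["bank"]["orientations_deg"] = tuple(d["bank"]["orientations_deg"])
        return cls(
            grid=GridSpec(**d["grid"]),
            bank=OrientationBank(**d["bank"]),
            qc=QCConfig(**d["qc"]),
            exclusion=ExclusionConfig(**d["exclusion"]),
            selection=SelectionConfig(**d["selection"]),
            viewing=ViewingGeometry(**d["viewing"]),
            objectness_threshold=d["objectness_threshold"],
            seed=d["seed"],
        )

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def child_seed(self, index: int) -> int:
        """Deterministic per-image seed below 2**31."""
        ss = np.random.SeedSequence([self.seed, index])
        return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(
    config: PipelineConfig,
    sources: dict,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run the full generation chain over ``sources`` (id -> image array/path).

    Returns a per-image summary table (QC verdicts plus metrics for the
    survivors).  Unreadable sources are logged and skipped; if every source
    fails, a RuntimeError is raised.
    """
    if not sources:
        raise ValueError("no source images given")
    grid = HexGrid(config.grid)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        for sub in ("stimuli", "features"):
            (out / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    n_fail_count = n_fail_disjoint = n_error = 0
    for index, (image_id, raw) in enumerate(sorted(sources.items())):
        try:
            img = preprocess(raw, config.grid)
        except Exception as exc:  # noqa: BLE001 - batch robustness
            log.warning("skipping %s: %s", image_id, exc)
            n_error += 1
            continue
        fl = featurize(img, config.grid, config.bank,
                       config.objectness_threshold, preprocessed=True)
        report = apply_qc(fl, config.grid, config.qc)
        row = {
            "image": image_id,
            "n_features": report.n_features,
            "n_regions": report.n_regions,
            "passed_qc": report.passed,
        }
        if report.passed:
            seed = config.child_seed(index)
            rng = np.random.default_rng(seed)
            background = choose_background(rng, config.bank)
            stim = render_stimulus(fl, background, config.grid, rng_seed=seed)
            m = compute_metrics(fl, background, config.grid,
                                config.bank.orientations_deg, config.qc)
            row.update({"background_deg": background, **m.to_dict()})
            if out is not None:
                stim.save(out / "stimuli" / f"{image_id}.png")
                meta = (out / "stimuli" / f"{image_id}.json")
                doc = yaml.safe_load(meta.read_text()) if meta.exists() else {}
                doc.update({"config_hash": config.config_hash,
                            "background_deg": background, "rng_seed": seed})
                meta.write_text(yaml.safe_dump(doc, sort_keys=True))
                fl.to_json(out / "features" / f"{image_id}.json")
        else:
            n_fail_count += not report.passes_count
            n_fail_disjoint += not report.passes_disjointedness
        rows.append(row)
    if not rows:
        raise RuntimeError("all source images failed to load")
    table = pd.DataFrame(rows).set_index("image")
    log.info(
        "pipeline: %d generated, %d failed count filter, %d failed "
        "disjointedness, %d unreadable",
        int(table["passed_qc"].sum()), n_fail_count, n_fail_disjoint, n_error,
    )
    if out is not None:
        table.to_csv(out / "qc_report.csv")
        passed = table[table["passed_qc"]]
        passed.to_csv(out / "metrics.csv")
        (out / "config.yaml").write_text(config.to_yaml())
    return table


_TABLE_COLUMNS = {
    "twoafc": ["observer", "session", "image_a", "image_b", "chosen"],
    "yesno": ["participant", "image", "response"],
    "naming": ["participant", "image", "label"],
}


def read_response_table(path, kind: str) -> pd.DataFrame:
    """Read a behavioral CSV and validate its schema.

    ``kind`` is one of twoafc / yesno / naming; yes-no response tokens are
    checked and the offending row named on failure.
    """
    if kind not in _TABLE_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(_TABLE_COLUMNS[kind]) - set(df.columns)
    if missing:
        raise ValueError(f"{kind} table missing columns {sorted(missing)}")
    if kind == "yesno":
        bad = ~df["response"].isin({"yes", "no", "timeout"})
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"invalid response {df['response'].iloc[row]!r} at row {row}"
            )
    return df
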