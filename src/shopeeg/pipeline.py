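"""End-to-end experiment orchestration from a declarative config.

``run_experiment`` chains the stages — simulate (or load), preprocess,
segment + tag, featurize, cross-validate — and writes a results bundle:
feature tables (CSV), per-run results JSON, a leaderboard CSV (rows =
model family, columns keyed by parameter/tau/CV scheme) and a manifest
accounting for every episode kept or dropped at each stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feats
from . import io as sio
from . import modeling, preprocess, segment, simulate

__all__ = ["ExperimentConfig", "run_experiment", "write_bundles", "load_bundles"]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    # data source: synthetic generator settings, or paths to recordings
    synthetic: dict = field(default_factory=dict)
    data_paths: list[str] | None = None  # matrix-sidecar JSONs; None -> synthetic
    events_path: str | None = None
    montage_path: str | None = None

    # preprocessing
    apply_filters: bool = True
    highpass_hz: float = 0.5
    notch_band: tuple[float, float] = (48.0, 52.0)
    literal_bandpass: bool = False
    rereference: bool = True
    reject_threshold_uv: float | None = None  # None = off (synthetic default)

    # analysis grid
    schemes: list[str] = field(default_factory=lambda: ["two_class"])
    parameters: list[str] = field(default_factory=lambda: ["mobility"])
    taus_ms: list[int] = field(default_factory=lambda: [1200])
    cv_schemes: list[str] = field(default_factory=lambda: ["kfold5", "loso"])
    model_families: list[str] = field(default_factory=lambda: list(modeling.MODEL_FAMILIES))
    normalize: bool = True
    placement: str = "centered"
    importance: bool = True

    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self):
        bad = set(self.taus_ms) - set(feats.TAUS_MS)
        if bad:
            raise ValueError(f"unsupported tau values {sorted(bad)}; supported: {feats.TAUS_MS}")
        bad = set(self.schemes) - set(segment.SCHEMES)
        if bad:
            raise ValueError(f"unknown label schemes {sorted(bad)}")
        bad = set(self.model_families) - set(modeling.MODEL_FAMILIES)
        if bad:
            raise ValueError(f"unknown model families {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "notch_band" in payload:
            payload["notch_band"] = tuple(payload["notch_band"])
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["notch_band"] = list(self.notch_band)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_bundles(bundles, out_dir) -> None:
    """Serialize session bundles (matrix recordings + events CSV + montage)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for b in bundles:
        sio.write_recording(b.recording, out_dir / f"{b.subject_id}_eeg", format="matrix")
        frames.append(b.events)
    sio.write_events(pd.concat(frames, ignore_index=True), out_dir / "events.csv")
    if bundles and bundles[0].montage is not None:
        bundles[0].montage.to_json(out_dir / "montage.json")


def load_bundles(data_paths, events_path, montage_path=None):
    """Rebuild session bundles from serialized stage outputs."""
    events = sio.read_events(events_path)
    montage = sio.Montage.from_json(montage_path) if montage_path else sio.Montage.standard_63()
    bundles = []
    for path in data_paths:
        rec = sio.read_recording(path, montage=montage)
        subject_id = Path(path).stem.removesuffix("_eeg")
        sub_events = events[events["subject_id"] == subject_id].reset_index(drop=True)
        bundles.append(simulate.SessionBundle(
            recording=rec, events=sub_events, subject_id=subject_id,
            ground_truth_labels=[], montage=montage,
        ))
    return bundles


def _preprocess_recording(rec, cfg: ExperimentConfig):
    if cfg.apply_filters:
        spec = preprocess.FilterSpec(
            highpass_hz=cfg.highpass_hz,
            notch_band_hz=tuple(cfg.notch_band),
            literal_bandpass=cfg.literal_bandpass,
        )
        rec = preprocess.apply_filters(rec, spec)
    if cfg.rereference:
        rec = preprocess.rereference_average(rec)
    return rec


def build_cohort_features(
    bundles,
    label_scheme: str = "two_class",
    parameter: str = "mobility",
    tau_ms: int = 1200,
    cfg: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Preprocess, segment, tag and featurize a cohort into one table."""
    cfg = cfg or ExperimentConfig()
    tables = []
    counts = {"episodes": 0, "artifact_dropped": 0, "boundary_skipped": 0}
    for bundle in bundles:
        rec = _preprocess_recording(bundle.recording, cfg)
        episodes = segment.segment_episodes(bundle.events)
        counts["episodes"] += len(episodes)
        if cfg.reject_threshold_uv:
            spans = preprocess.reject_artifact_spans(rec, cfg.reject_threshold_uv)
            episodes, dropped = preprocess.drop_episodes_in_spans(episodes, spans)
            counts["artifact_dropped"] += len(dropped)
        if label_scheme == "two_class":
            labeled = segment.label_two_class(episodes, bundle.events)
        else:
            labeled = segment.label_three_class(episodes, bundle.events)
        df = feats.build_feature_table(
            rec, labeled, taus_ms=(tau_ms,), parameter=parameter,
            normalize=cfg.normalize, placement=cfg.placement,
        )
        counts["boundary_skipped"] += df.attrs.get("n_skipped_episodes", 0)
        tables.append(df)
    out = pd.concat(tables, ignore_index=True)
    out.attrs.update(counts)
    return out


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full grid; returns the manifest (also written to disk)."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cfg.data_paths:
        bundles = load_bundles(cfg.data_paths, cfg.events_path, cfg.montage_path)
    else:
        gen_cfg = simulate.GeneratorConfig(**{**cfg.synthetic, "seed": cfg.seed})
        bundles = simulate.generate_cohort(gen_cfg)

    leaderboard_rows = []
    results = []
    manifest_counts = {}
    for label_scheme in cfg.schemes:
        for parameter in cfg.parameters:
            for tau in cfg.taus_ms:
                logger.info("featurizing %s / %s / tau=%d", label_scheme, parameter, tau)
                table = build_cohort_features(bundles, label_scheme, parameter, tau, cfg)
                key = f"{label_scheme}_{parameter}_tau{tau}"
                manifest_counts[key] = {**table.attrs, "snippets": len(table)}
                table.to_csv(out_dir / f"features_{key}.csv", index=False)
                for family in cfg.model_families:
                    spec = modeling.ModelSpec(family=family, seed=cfg.seed)
                    decoder = modeling.PurchaseDecoder(table, spec)
                    for cv_scheme in cfg.cv_schemes:
                        if cv_scheme == "loso" and table["subject_id"].nunique() < 2:
                            continue
                        cv = decoder.cross_validate(cv_scheme)
                        results.append({
                            "label_scheme": label_scheme, "parameter": parameter,
                            "tau_ms": tau, **cv.to_dict(),
                        })
                        leaderboard_rows.append({
                            "model": family, "label_scheme": label_scheme,
                            "parameter": parameter, "tau_ms": tau,
                            "cv": cv_scheme, "balanced_accuracy": round(cv.mean, 4),
                            "sd": round(cv.sd, 4),
                        })
                if cfg.importance and "random_forest" in cfg.model_families:
                    spec = modeling.ModelSpec(family="random_forest", seed=cfg.seed)
                    fitted = modeling.PurchaseDecoder(table, spec).fit()
                    imp = fitted.channel_importance("impurity")
                    imp.to_frame().to_csv(out_dir / f"importance_{key}.csv", index=False)

    leaderboard = pd.DataFrame(leaderboard_rows)
    leaderboard.to_csv(out_dir / "leaderboard.csv", index=False)
    (out_dir / "results.json").write_text(json.dumps(results, indent=1))
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.content_hash(),
        "n_subjects": len(bundles),
        "counts": manifest_counts,
        "n_leaderboard_rows": len(leaderboard_rows),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
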