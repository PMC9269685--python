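"""End-to-end orchestration: simulate -> harmonize -> segment -> extract ->
reliability / agreement, as one configured, logged run.

A run is driven by a YAML/dict config, executes the stages in order, writes
per-stage outputs under the output directory and finishes with a JSON
manifest (seed, config hash, per-trial status).  A trial that fails in any
stage is recorded with its reason and excluded from the statistics — never
silently dropped; the run only aborts on configuration errors.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import TransferKinError
from .features import extract_features
from .harmonize import harmonize
from .io import read_recording, write_recording
from .reliability import reliability_report
from .agreement import accuracy_vs_truth, percent_agreement
from .segmentation import detect_phases
from .simulate import SensorNoiseModel, SessionDesign, TransferProfile, simulate_session

log = logging.getLogger("transferkin.pipeline")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: Path
    seed: int = 0
    side: str = "left"
    transverse: str = "trunk"
    filter_cutoff: float = 15.0
    filter_order: int = 4
    zero_phase: bool = True
    design: SessionDesign = field(default_factory=SessionDesign)
    write_recordings: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict, outdir: str | Path) -> "RunConfig":
        raw = dict(raw)
        design_raw = dict(raw.pop("design", {}))
        sensors = {
            name: SensorNoiseModel(**(spec or {}))
            for name, spec in design_raw.pop(
                "sensors", {"kinect_azure": {}, "kinect_v2": {}}
            ).items()
        }
        profile = TransferProfile(**design_raw.pop("base_profile", {}))
        if "plan" in design_raw:
            design_raw["plan"] = tuple(design_raw["plan"])
        design = SessionDesign(sensors=sensors, base_profile=profile, **design_raw)
        return cls(outdir=Path(outdir), design=design, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {}, outdir)

    def content_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "side": self.side,
            "transverse": self.transverse,
            "filter_cutoff": self.filter_cutoff,
            "filter_order": self.filter_order,
            "zero_phase": self.zero_phase,
            "design": asdict(self.design),
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _process_recording(seq, config: RunConfig) -> dict:
    canon = harmonize(seq, side=config.side)
    pelvis_x = canon.positions["pelvis"][:, 0].copy()
    pelvis_x[~canon.valid["pelvis"]] = float("nan")
    rate = seq.sensor.nominal_rate
    seg = detect_phases(
        pelvis_x,
        rate,
        cutoff=config.filter_cutoff,
        order=config.filter_order,
        zero_phase=config.zero_phase,
    )
    fs = extract_features(canon, seg, transverse=config.transverse)
    row = fs.as_dict()
    row["lift_start_idx"] = seg.lift_start_idx
    row["lift_end_idx"] = seg.lift_end_idx
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full simulated-session run; returns the manifest dict."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    session = simulate_session(config.design, seed=config.seed)
    session.truth_features.to_csv(outdir / "truth_features.csv", index=False)
    session.truth_scores.to_csv(outdir / "truth_scores.csv")

    trial_status: list[dict] = []
    feature_tables: dict[str, pd.DataFrame] = {}
    for sensor_name, seqs in session.recordings.items():
        rows = []
        rec_dir = outdir / "recordings" / sensor_name
        if config.write_recordings:
            rec_dir.mkdir(parents=True, exist_ok=True)
        for seq in seqs:
            if config.write_recordings:
                path = rec_dir / f"{seq.trial_id}.csv"
                write_recording(seq, path)
                seq = read_recording(path, seq.sensor, seq.trial_id, seq.subject_id)
            try:
                rows.append(_process_recording(seq, config))
                trial_status.append(
                    {"sensor": sensor_name, "trial_id": seq.trial_id, "status": "ok"}
                )
            except TransferKinError as exc:
                log.warning("trial %s/%s failed: %s", sensor_name, seq.trial_id, exc)
                trial_status.append(
                    {
                        "sensor": sensor_name,
                        "trial_id": seq.trial_id,
                        "status": "failed",
                        "reason": str(exc),
                    }
                )
        table = pd.DataFrame(rows)
        feature_tables[sensor_name] = table
        table.to_csv(outdir / f"features_{sensor_name}.csv", index=False)

    report = None
    usable = {
        s: t for s, t in feature_tables.items() if len(t) >= 4
    }
    if len(usable) >= 2:
        report = reliability_report(usable)
        report.inter.to_csv(outdir / "reliability_inter.csv", index=False)
        report.intra.to_csv(outdir / "reliability_intra.csv", index=False)
        with open(outdir / "reliability.json", "w") as fh:
            json.dump(report.to_json(), fh, indent=2, default=str)

    agreement_summary = None
    sensors = list(session.predicted_scores)
    for sensor_name, table in session.predicted_scores.items():
        table.to_csv(outdir / f"predicted_scores_{sensor_name}.csv")
    if len(sensors) >= 2:
        agr = percent_agreement(
            session.predicted_scores[sensors[0]], session.predicted_scores[sensors[1]]
        )
        agr.per_item.to_csv(outdir / "score_agreement.csv", index=False)
        agreement_summary = {
            "overall_mean_percent": agr.overall_mean_percent,
            "overall_std_percent": agr.overall_std_percent,
        }
    accuracy_tables = {}
    for sensor_name in sensors:
        acc = accuracy_vs_truth(session.predicted_scores[sensor_name], session.truth_scores)
        acc.accuracy.to_csv(outdir / f"score_accuracy_{sensor_name}.csv")
        accuracy_tables[sensor_name] = {
            c: acc.accuracy[c].mean() for c in acc.accuracy.columns
        }

    n_failed = sum(1 for t in trial_status if t["status"] == "failed")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "n_trials": len(trial_status),
        "n_failed": n_failed,
        "trials": trial_status,
        "agreement": agreement_summary,
        "mean_accuracy_by_type": accuracy_tables,
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
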