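"""Serialization: recordings as CSV + JSON sidecars, feature tables as
CSV, reports as JSON/CSV, and reproducibility manifests.

All artifacts are diffable text; the data volumes involved are small
enough that a binary container would only hurt inspectability.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import FeatureDataset
from .types import (
    ClassifierConfig,
    EvalReport,
    Family,
    Recording,
    RhythmLabel,
    SensorPlacement,
    SpectrumSetting,
)


# ---------------------------------------------------------------------------
# Recordings

def save_recording(rec: Recording, out_dir: Path) -> Path:
    """Write one participant as ``<id>.csv`` (sample_index, bcg1..bcg4)
    plus a ``<id>.json`` sidecar with identity and sampling metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame({"sample_index": np.arange(rec.n_samples)})
    for placement, signal in rec.channels.items():
        frame[placement.value.lower()] = signal
    csv_path = out_dir / f"{rec.participant_id}.csv"
    frame.to_csv(csv_path, index=False)
    sidecar = {
        "participant_id": rec.participant_id,
        "label": rec.label.value,
        "fs": rec.fs,
        "mean_hr_bpm": rec.mean_hr_bpm,
        "placements": [p.value for p in rec.channels],
    }
    (out_dir / f"{rec.participant_id}.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )
    return csv_path


def load_recording(out_dir: Path, participant_id: str) -> Recording:
    out_dir = Path(out_dir)
    sidecar = json.loads((out_dir / f"{participant_id}.json").read_text())
    frame = pd.read_csv(out_dir / f"{participant_id}.csv")
    channels = {
        SensorPlacement(name): frame[name.lower()].to_numpy(dtype=np.uint16)
        for name in sidecar["placements"]
    }
    return Recording(
        participant_id=sidecar["participant_id"],
        label=RhythmLabel(sidecar["label"]),
        channels=channels,
        fs=float(sidecar["fs"]),
        mean_hr_bpm=sidecar.get("mean_hr_bpm"),
    )


def save_cohort(recordings: Sequence[Recording], out_dir: Path) -> Path:
    """Write every recording plus a cohort ``manifest.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        save_recording(rec, out_dir)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "label": rec.label.value,
                "fs": rec.fs,
                "n_samples": rec.n_samples,
                "file": f"{rec.participant_id}.csv",
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(out_dir: Path) -> List[Recording]:
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv")
    return [load_recording(out_dir, pid) for pid in manifest["participant_id"]]


# ---------------------------------------------------------------------------
# Features

def setting_to_dict(setting: SpectrumSetting) -> dict:
    return {
        "lowcut_hz": setting.lowcut_hz,
        "highcut_hz": setting.highcut_hz,
        "nbins": setting.nbins,
    }


def setting_from_dict(d: Mapping) -> SpectrumSetting:
    return SpectrumSetting(
        lowcut_hz=float(d["lowcut_hz"]),
        highcut_hz=float(d["highcut_hz"]),
        nbins=int(d["nbins"]),
    )


def save_features(dataset: FeatureDataset, setting: SpectrumSetting, path: Path) -> Path:
    """One row per included block: identity columns then feature_0..n-1;
    a JSON sidecar records the setting and the pre-screening block count."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    X = dataset.features[setting]
    frame = dataset.meta.copy()
    frame["included"] = True
    for j in range(setting.nbins):
        frame[f"feature_{j}"] = X[:, j]
    frame.to_csv(path, index=False)
    sidecar = {
        "setting": setting_to_dict(setting),
        "n_total_blocks": dataset.n_total_blocks,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def load_features(path: Path) -> FeatureDataset:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    setting = setting_from_dict(sidecar["setting"])
    frame = pd.read_csv(path)
    frame = frame[frame["included"]]
    X = frame[[f"feature_{j}" for j in range(setting.nbins)]].to_numpy(dtype=float)
    meta = frame[["participant_id", "placement", "start_sample", "label"]].reset_index(
        drop=True
    )
    return FeatureDataset(
        meta=meta,
        features={setting: X},
        n_total_blocks=int(sidecar["n_total_blocks"]),
    )


# ---------------------------------------------------------------------------
# Configs and reports

def config_to_dict(config: ClassifierConfig) -> dict:
    return {
        "family": config.family.value,
        "hyperparameters": config.params,
        "setting": setting_to_dict(config.setting),
    }


def config_from_dict(d: Mapping) -> ClassifierConfig:
    return ClassifierConfig.make(
        Family(d["family"]),
        setting_from_dict(d["setting"]),
        **d["hyperparameters"],
    )


def report_to_dict(report: EvalReport, rounded: bool = False) -> dict:
    return report.rounded() if rounded else asdict(report)


def save_json(obj, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
    return path


# ---------------------------------------------------------------------------
# Run manifest

def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: with equal seed, config hash and software
    versions, a rerun produces byte-identical data artifacts."""

    seed: int
    config: dict
    config_hash: str
    versions: Dict[str, str]
    digests: Dict[str, str] = field(default_factory=dict)
    created_utc: str = ""

    @staticmethod
    def build(seed: int, config: dict, files: Iterable[Path] = (),
              root: Optional[Path] = None) -> "RunManifest":
        import sklearn

        import bcgaf

        canonical = json.dumps(config, sort_keys=True, default=str)
        digests = {}
        for f in files:
            f = Path(f)
            key = str(f.relative_to(root)) if root else f.name
            digests[key] = sha256_file(f)
        return RunManifest(
            seed=seed,
            config=config,
            config_hash=hashlib.sha256(canonical.encode()).hexdigest(),
            versions={
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
                "bcgaf": bcgaf.__version__,
            },
            digests=digests,
            created_utc=datetime.now(timezone.utc).isoformat(),
        )

    def save(self, path: Path) -> Path:
        return save_json(asdict(self), path)
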