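"""End-to-end pipeline driver: simulate -> featurize -> train ->
evaluate -> transfer -> fuse, with all intermediate artifacts written as
CSV/JSON and a run manifest for reproducibility.

The pipeline is configured by a single YAML/JSON document with sections
``simulate``, ``featurize``, ``train`` and ``fuse``; every stage logs to
stderr with its wall time. Reruns with the same seed and config produce
identical data artifacts.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import classify, fuse as fuse_mod, io as io_mod, synth
from .preprocess import FeatureDataset, featurize_recordings, n_blocks
from .types import (
    BLOCK_SECONDS,
    RAW_NOISE_THRESHOLD,
    STRIDE_SECONDS,
    ClassifierConfig,
    NoiseRule,
    SensorPlacement,
    SynthParams,
)

log = logging.getLogger("bcgaf")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "bcgaf_run",
    "simulate": {
        "n_af_train": 4,
        "n_non_af_train": 7,
        "n_af_test": 2,
        "n_non_af_test": 3,
        "duration_s": 300.0,
    },
    "featurize": {"noise_rule": "raw", "threshold": RAW_NOISE_THRESHOLD},
    "train": {
        "placement": "BCG2",
        "k": 5,
        "families": ["ADA"],
        "settings": [
            {"lowcut_hz": 0.0, "highcut_hz": 10.0, "nbins": 30},
            {"lowcut_hz": 1.0, "highcut_hz": 10.0, "nbins": 30},
        ],
        "hyperparameters": {"ADA": {"learning_rate": [1.0, 0.9], "max_depth": [1, 7]}},
        "loocv": False,
    },
    "fuse": {"subsets": [["BCG1", "BCG2"], ["BCG1", "BCG2", "BCG3", "BCG4"]]},
}


def load_config(source) -> dict:
    """Accept a dict, a YAML/JSON path, or None (built-in demo config);
    unspecified keys fall back to the demo defaults."""
    if source is None:
        cfg: dict = {}
    elif isinstance(source, Mapping):
        cfg = dict(source)
    else:
        cfg = yaml.safe_load(Path(source).read_text()) or {}
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in cfg.items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def build_synth_params(sim_cfg: Mapping) -> SynthParams:
    """SynthParams from the ``simulate`` config section; any field of
    SynthParams may be overridden by name."""
    known = {
        k: v
        for k, v in sim_cfg.items()
        if k in SynthParams.__dataclass_fields__
    }
    return SynthParams(**known)


def build_grid(train_cfg: Mapping) -> List[ClassifierConfig]:
    """Configs from the ``train`` section, in deterministic grid order
    (family order, then hyperparameters in table order, then settings)."""
    settings = [io_mod.setting_from_dict(s) for s in train_cfg["settings"]]
    configs: List[ClassifierConfig] = []
    hyper = train_cfg.get("hyperparameters", {})
    for family in classify.FAMILY_ORDER:
        if family.value not in train_cfg["families"]:
            continue
        names = list(classify.TABLE_HYPERPARAMETERS[family])
        grids = hyper.get(family.value, {})
        value_lists = [
            grids.get(n, classify.TABLE_HYPERPARAMETERS[family][n]) for n in names
        ]
        for values in itertools.product(*value_lists):
            for setting in settings:
                configs.append(
                    ClassifierConfig.make(family, setting, **dict(zip(names, values)))
                )
    return configs


def _stage(name: str):
    log.info("stage %s ...", name)
    return time.perf_counter()


def _done(name: str, t0: float) -> None:
    log.info("stage %s done in %.1f s", name, time.perf_counter() - t0)


def run_pipeline(config=None, out_dir: Optional[Path] = None) -> Path:
    """Execute every stage on a synthetic cohort and return the output
    directory containing all artifacts plus ``summary.json`` and
    ``manifest.json``."""
    cfg = load_config(config)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    root_ss = np.random.SeedSequence(seed)
    seed_train, seed_test, seed_cv = (
        int(s) for s in (root_ss.generate_state(3) & 0x7FFFFFFF)
    )

    # -- simulate ----------------------------------------------------------
    t0 = _stage("simulate")
    sim = cfg["simulate"]
    params = build_synth_params(sim)
    train_cohort = synth.generate_cohort(
        int(sim["n_af_train"]), int(sim["n_non_af_train"]), params, seed_train
    )
    test_cohort = synth.generate_cohort(
        int(sim["n_af_test"]), int(sim["n_non_af_test"]), params, seed_test
    )
    # Test participants get ids disjoint from training ones.
    for rec in test_cohort:
        rec.participant_id = "T" + rec.participant_id[1:]
    io_mod.save_cohort(train_cohort, out / "recordings" / "train")
    io_mod.save_cohort(test_cohort, out / "recordings" / "test")
    _done("simulate", t0)

    # -- featurize ---------------------------------------------------------
    t0 = _stage("featurize")
    feat = cfg["featurize"]
    rule = (
        NoiseRule.RAW_THRESHOLD
        if feat["noise_rule"] == "raw"
        else NoiseRule.STD_THRESHOLD
    )
    threshold = float(feat["threshold"])
    settings = [io_mod.setting_from_dict(s) for s in cfg["train"]["settings"]]
    train_placement = SensorPlacement(cfg["train"]["placement"])

    train_ds = featurize_recordings(
        train_cohort, [train_placement], settings, rule, threshold
    )
    test_ds_by_placement: Dict[SensorPlacement, FeatureDataset] = {
        pl: featurize_recordings(test_cohort, [pl], settings, rule, threshold)
        for pl in SensorPlacement
    }
    artifacts = []
    for setting in settings:
        artifacts.append(
            io_mod.save_features(
                train_ds, setting, out / "features" / f"train_{train_placement.value}_{setting}.csv"
            )
        )
    for pl, ds in test_ds_by_placement.items():
        artifacts.append(
            io_mod.save_features(
                ds, settings[0], out / "features" / f"test_{pl.value}_{settings[0]}.csv"
            )
        )
    _done("featurize", t0)

    # -- train -------------------------------------------------------------
    t0 = _stage("train")
    grid = build_grid(cfg["train"])
    best, all_results = classify.grid_search(
        train_ds, grid, k=int(cfg["train"]["k"]), seed=seed_cv, return_all=True
    )
    model = classify.fit_model(
        train_ds.features[best.config.setting],
        train_ds.meta["label"].to_numpy(),
        best.config,
        seed=seed_cv,
    )
    summary: dict = {
        "seed": seed,
        "best_config": io_mod.config_to_dict(best.config),
        "cv_mean_accuracy": best.mean_accuracy,
        "cv_sd_accuracy": best.sd_accuracy,
        "grid_size": len(grid),
        "train_blocks_included": train_ds.n_included,
        "train_blocks_total": train_ds.n_total_blocks,
    }
    if cfg["train"].get("loocv"):
        loocv_table, loocv_mean, loocv_sd = classify.loocv_by_participant(
            train_ds, best.config, seed=seed_cv
        )
        loocv_table.to_csv(out / "loocv.csv", index=False)
        summary["loocv_mean_accuracy"] = loocv_mean
        summary["loocv_sd_accuracy"] = loocv_sd
    io_mod.save_json(io_mod.config_to_dict(best.config), out / "best_config.json")
    _done("train", t0)

    # -- evaluate + transfer ----------------------------------------------
    t0 = _stage("transfer")
    preds_by_sensor = {}
    transfer = {}
    for pl, ds in test_ds_by_placement.items():
        if ds.n_included == 0:
            continue
        report, preds = classify.cross_location_apply(model, ds)
        preds_by_sensor[pl] = preds
        transfer[pl.value] = io_mod.report_to_dict(report)
        rows = [
            {
                "participant_id": p.participant_id,
                "placement": p.placement.value,
                "start_sample": p.start_sample,
                "predicted": p.predicted.value,
                "score": p.score,
            }
            for p in preds
        ]
        pd.DataFrame(rows).to_csv(out / f"predictions_{pl.value}.csv", index=False)
    summary["test_report"] = transfer.get(train_placement.value)
    summary["transfer_reports"] = transfer
    _done("transfer", t0)

    # -- fuse --------------------------------------------------------------
    t0 = _stage("fuse")
    labels = {rec.participant_id: rec.label for rec in test_cohort}
    block_len = int(round(BLOCK_SECONDS * params.fs))
    stride = int(round(STRIDE_SECONDS * params.fs))
    total_aligned = sum(
        n_blocks(rec.n_samples, block_len, stride) for rec in test_cohort
    )
    fusion_rows = []
    for subset_names in cfg["fuse"]["subsets"]:
        subset = frozenset(SensorPlacement(s) for s in subset_names)
        fused = fuse_mod.combine_or(preds_by_sensor, subset)
        rep = fuse_mod.fusion_report(fused, labels, total_blocks=total_aligned)
        row = {
            "subset": "+".join(sorted(p.value for p in subset)),
            "included_blocks": rep.included_blocks,
            "included_fraction": rep.included_fraction,
        }
        row.update(io_mod.report_to_dict(rep.report))
        fusion_rows.append(row)
    pd.DataFrame(fusion_rows).to_csv(out / "fusion.csv", index=False)
    summary["fusion"] = fusion_rows
    _done("fuse", t0)

    # -- summary + manifest ------------------------------------------------
    io_mod.save_json(summary, out / "summary.json")
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    hashed_cfg = {k: v for k, v in cfg.items() if k != "out_dir"}
    io_mod.RunManifest.build(seed, hashed_cfg, files, root=out).save(out / "manifest.json")
    return out
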