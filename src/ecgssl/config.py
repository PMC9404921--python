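"""YAML run configuration and the end-to-end experiment driver.

One :class:`RunConfig` describes a full run: synthetic-data generation (or
ingestion), preprocessing, pretext augmentation, encoder/projection
architecture, upstream and downstream optimizer settings, and the
evaluation protocol.  Defaults follow the affect-study conventions this
package targets (256 Hz, 0.8 Hz high-pass, 10 s windows, upstream Adam
1e-4 / batch 32 / 20 epochs, downstream Adam 1e-3 / batch 128 / 250
epochs, 10 shuffled folds).  Precedence is CLI > file > defaults.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .augment import AugmentationSpec
from .contrastive import ContrastivePretrainer, save_weights
from .evaluation import evaluate_pipeline
from .preprocess import EcgPreprocessor
from .records import SegmentSet
from .synthetic import ConditionSchedule, gen_dataset

__all__ = ["RunConfig", "load_config", "run_experiment", "DEFAULTS"]

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "runs/latest",
    "synth": {
        "n_subjects": 6,
        "fs": 256.0,
        "schedule": "0:60,1:60,2:60",  # condition:duration_s blocks
        "class_counts": None,
        "saturation_level": None,
    },
    "preprocess": {
        "fs_out": 256.0,
        "passband_hz": 0.8,
        "bound_sd": 10.0,
        "window_s": 10.0,
        "smote": False,
        "k_neighbors": 5,
    },
    "augment": "timewarp+scale",
    "encoder": {
        "filters": [32, 64, 128],
        "kernels": [32, 16, 8],
        "pool_size": 4,
        "dropout_rate": 0.1,
        "dense_units": 80,
        "l2_coeff": 3.0,
    },
    "projection": {"units": 256, "activation": "linear"},
    "upstream": {
        "learning_rate": 1e-4,
        "batch_size": 32,
        "epochs": 20,
        "temperature": 0.1,
    },
    "downstream": {"learning_rate": 1e-3, "batch_size": 128, "epochs": 250},
    "evaluation": {"test_ratio": 0.1, "n_folds": 10, "subject_wise": False},
}


class RunConfig(dict):
    """A validated configuration mapping (dot-path access via ``get_path``)."""

    def get_path(self, dotted: str):
        node = self
        for part in dotted.split("."):
            node = node[part]
        return node

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ValueError(f"unknown config key: {where}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, where)
        else:
            out[key] = val
    return out


def _validate(cfg: dict) -> None:
    checks = [
        ("upstream.temperature", lambda v: v > 0, "must be positive"),
        ("upstream.learning_rate", lambda v: v > 0, "must be positive"),
        ("downstream.learning_rate", lambda v: v > 0, "must be positive"),
        ("upstream.batch_size", lambda v: v >= 2, "must be >= 2"),
        ("evaluation.test_ratio", lambda v: 0 < v < 1, "must be in (0, 1)"),
        ("preprocess.window_s", lambda v: v > 0, "must be positive"),
        ("preprocess.passband_hz", lambda v: v > 0, "must be positive"),
        ("synth.fs", lambda v: v >= 64, "must be >= 64 Hz"),
    ]
    for dotted, ok, msg in checks:
        node = cfg
        for part in dotted.split("."):
            node = node[part]
        if not ok(node):
            raise ValueError(f"invalid config value at {dotted}: {node!r} ({msg})")
    AugmentationSpec.parse(cfg["augment"])  # raises on unknown names


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load defaults, merge a YAML file (if any) and overrides, validate."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    _validate(cfg)
    return RunConfig(cfg)


def parse_schedule(text: str) -> ConditionSchedule:
    """Parse 'cond:dur,cond:dur,...' (durations in seconds)."""
    blocks = []
    for part in text.split(","):
        code, dur = part.split(":")
        blocks.append((int(code), float(dur)))
    return ConditionSchedule(blocks)


def run_experiment(cfg: RunConfig, dry_run: bool = False) -> dict:
    """Execute synth -> preprocess -> pretrain -> fine-tune/evaluate.

    Writes the segment archive, pretrained encoder weights, per-epoch loss
    curve, fold report (JSON) and confusion matrix (CSV) into
    ``cfg['out_dir']``, each stamped with the config hash and seed.
    Returns a manifest of the artifact paths (empty when ``dry_run``).
    """
    if dry_run:
        return {"config_hash": cfg.config_hash(), "artifacts": {}}
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    records = gen_dataset(
        n_subjects=int(cfg["synth"]["n_subjects"]),
        schedule_template=parse_schedule(cfg["synth"]["schedule"]),
        fs=float(cfg["synth"]["fs"]),
        class_counts=cfg["synth"]["class_counts"],
        seed=seed,
        window_s=float(cfg["preprocess"]["window_s"]),
        saturation_level=cfg["synth"]["saturation_level"],
    )
    pre = EcgPreprocessor(seed=seed, **cfg["preprocess"])
    segs: SegmentSet = pre.transform(records)
    seg_path = out / "segments.npz"
    segs.to_npz(seg_path)

    up = cfg["upstream"]
    enc = cfg["encoder"]
    pretrainer = ContrastivePretrainer(
        augmentation=cfg["augment"],
        filters=tuple(enc["filters"]),
        kernels=tuple(enc["kernels"]),
        pool_size=enc["pool_size"],
        dropout_rate=enc["dropout_rate"],
        dense_units=enc["dense_units"],
        l2_coeff=enc["l2_coeff"],
        projection_units=cfg["projection"]["units"],
        projection_activation=cfg["projection"]["activation"],
        temperature=up["temperature"],
        learning_rate=up["learning_rate"],
        batch_size=up["batch_size"],
        epochs=up["epochs"],
        random_state=seed,
    ).fit(segs)
    w_path = out / "encoder_weights.npz"
    save_weights(pretrainer.encoder_weights_, w_path)
    loss_path = out / "upstream_loss.csv"
    np.savetxt(loss_path, np.column_stack([np.arange(1, len(pretrainer.loss_history_) + 1),
                                           pretrainer.loss_history_]),
               delimiter=",", header="epoch,mean_loss", comments="")

    ev = cfg["evaluation"]
    report = evaluate_pipeline(
        segs,
        "contrastive-ssl",
        test_ratio=float(ev["test_ratio"]),
        n_folds=int(ev["n_folds"]),
        base_seed=seed,
        augmentation=cfg["augment"],
        upstream={**{k: up[k] for k in ("temperature", "learning_rate", "batch_size", "epochs")},
                  **{k: tuple(v) if isinstance(v, list) else v for k, v in enc.items()},
                  "projection_units": cfg["projection"]["units"],
                  "projection_activation": cfg["projection"]["activation"]},
        downstream={"learning_rate": cfg["downstream"]["learning_rate"],
                    "batch_size": cfg["downstream"]["batch_size"],
                    "epochs": cfg["downstream"]["epochs"],
                    **{k: tuple(v) if isinstance(v, list) else v for k, v in enc.items()
                       if k in ("filters", "kernels")},
                    **{k: enc[k] for k in ("pool_size", "dropout_rate", "dense_units", "l2_coeff")}},
        subject_wise=bool(ev["subject_wise"]),
    )
    report.config_echo["config_hash"] = cfg.config_hash()
    report.config_echo["seed"] = seed
    rep_path = out / "fold_report.json"
    report.save(rep_path)
    conf_path = out / "confusion.csv"
    np.savetxt(conf_path, report.confusion, fmt="%d", delimiter=",")
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps({
        "config": cfg, "config_hash": cfg.config_hash(), "seed": seed,
        "n_segments": len(segs), "mean_accuracy": report.mean_accuracy,
        "sd_accuracy": report.sd_accuracy,
    }, indent=2, default=str))
    return {
        "config_hash": cfg.config_hash(),
        "mean_accuracy": report.mean_accuracy,
        "sd_accuracy": report.sd_accuracy,
        "artifacts": {
            "segments": str(seg_path),
            "encoder_weights": str(w_path),
            "upstream_loss": str(loss_path),
            "fold_report": str(rep_path),
            "confusion": str(conf_path),
            "run_log": str(log_path),
        },
    }
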