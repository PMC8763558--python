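"""End-to-end diagnosis pipeline: feature selection -> tuning -> classification.

Three stages, in a fixed order:

1. Wrapper feature selection with the tent-chaos sailfish optimizer on the
   full table.
2. Stratified outer cross-validation on the selected columns; within each
   training fold the rat swarm optimizer tunes the BiGRU hyperparameters by
   inner cross-validation (nested, so the test fold never influences the
   tuning).
3. A BiGRU trained per outer fold with its tuned hyperparameters predicts
   the held-out fold; per-fold confusion counts are summed into the
   aggregate report.

All randomness derives from one master seed: stage seeds are drawn from a
``numpy`` SeedSequence spawned from it in a fixed documented order (feature
selection first, then one tuning and one training seed per outer fold), so
a run is byte-reproducible from its config and master seed alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import __version__
from .data import EvalReport, SyntheticSpec, TabularDataset, evaluate, generate_synthetic, load_tabular
from .features import FSResult, select_features
from .gru import BiGRUClassifier
from .ratswarm import HyperSpace, RSOConfig, tune_bigru

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

_DEFAULTS: dict = {
    "seed": 0,
    "dataset": {"synthetic": {}},  # or {"path": ..., "label_column": ..., "positive_label": ...}
    "chaos": {"t0": 0.9},
    "sfo": {"num_sardines": 60, "percent": 0.3, "A": 4.0, "epsilon": 0.001, "max_iter": 500},
    "fs": {"enabled": True, "omega": 0.99, "box": 4.0, "folds": 5, "evaluator": "knn1"},
    "rso": {"pop_size": 4, "max_iter": 3},
    "bigru": {
        "space": {"hidden_log2": [2.0, 6.0], "lr_log10": [-4.0, -1.0], "epochs": [10.0, 100.0]},
        "batch_size": 16,
    },
    "cv": {"outer_folds": 10, "inner_folds": 3},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass(frozen=True)
class RunConfig:
    """Fully-resolved pipeline configuration (defaults merged in)."""

    raw: dict

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(_merge(_DEFAULTS, d or {}))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str):
        return self.raw[key]

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a pipeline run produced, reproducible from config + seed."""

    config_hash: str
    master_seed: int
    n_features_total: int
    fs: dict | None
    fold_reports: list[dict]
    fold_hyperparameters: list[dict]
    aggregate: dict
    version: str = __version__
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "master_seed": self.master_seed,
            "n_features_total": self.n_features_total,
            "feature_selection": self.fs,
            "fold_hyperparameters": self.fold_hyperparameters,
            "fold_reports": self.fold_reports,
            "aggregate": self.aggregate,
            "version": self.version,
            "timestamp": self.timestamp,
        }

    def summary(self) -> str:
        """Human-readable summary mirroring the benchmark-table layouts."""
        lines = ["Feature selection", "dataset\ttotal features\tselected features"]
        sel = self.fs["n_selected"] if self.fs else self.n_features_total
        lines.append(f"run\t{self.n_features_total}\t{sel}")
        lines.append("")
        lines.append("Classification (aggregated over outer CV folds)")
        lines.append("Accuracy\tDR\tFAR")
        a = self.aggregate
        lines.append(f"{a['accuracy']:.3f}\t{a['DR']:.3f}\t{a['FAR']:.3f}")
        return "\n".join(lines)


def _load_dataset(cfg: RunConfig) -> TabularDataset:
    ds = cfg["dataset"]
    if "path" in ds:
        return load_tabular(ds["path"], ds.get("label_column", "label"), ds.get("positive_label", 1))
    spec = SyntheticSpec(**ds.get("synthetic", {}))
    return generate_synthetic(spec)


def _stage_seeds(master_seed: int, outer_folds: int) -> dict:
    """Fixed spawn order: fs, then (tune, train) per outer fold."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(1 + 2 * outer_folds)
    as_int = [int(c.generate_state(1)[0]) % (2**31) for c in children]
    return {
        "fs": as_int[0],
        "tune": as_int[1 : 1 + outer_folds],
        "train": as_int[1 + outer_folds :],
    }


def run_pipeline(config: RunConfig, output_dir=None) -> RunReport:
    """Execute the three-stage pipeline; optionally write the report to disk."""
    dataset = _load_dataset(config)
    outer_folds = config["cv"]["outer_folds"]
    inner_folds = config["cv"]["inner_folds"]
    seeds = _stage_seeds(config["seed"], outer_folds)

    fs_cfg = config["fs"]
    fs_result: FSResult | None = None
    if fs_cfg.get("enabled", True):
        try:
            fs_result = select_features(
                dataset,
                num_sardines=config["sfo"]["num_sardines"],
                percent=config["sfo"]["percent"],
                A=config["sfo"]["A"],
                epsilon=config["sfo"]["epsilon"],
                max_iter=config["sfo"]["max_iter"],
                seed=seeds["fs"],
                omega=fs_cfg["omega"],
                box=fs_cfg["box"],
                folds=fs_cfg["folds"],
                evaluator=fs_cfg["evaluator"],
                t0=config["chaos"]["t0"],
            )
        except Exception as exc:  # pragma: no cover - abort contract
            raise RuntimeError(f"feature-selection stage failed: {exc}") from exc
        mask = fs_result.mask
    else:
        mask = np.ones(dataset.n_features, dtype=np.int8)

    masked = dataset.masked(mask)
    space_cfg = config["bigru"]["space"]
    space = HyperSpace(
        hidden_log2=tuple(space_cfg["hidden_log2"]),
        lr_log10=tuple(space_cfg["lr_log10"]),
        epochs=tuple(space_cfg["epochs"]),
    )

    skf = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=config["seed"] % (2**31))
    fold_reports: list[dict] = []
    fold_hps: list[dict] = []
    total: EvalReport | None = None

    for k, (tr, te) in enumerate(skf.split(masked.X, masked.y)):
        train_ds = TabularDataset(
            masked.X[tr], masked.y[tr], masked.feature_names, masked.positive_label
        )
        try:
            rso_cfg = RSOConfig(
                pop_size=config["rso"]["pop_size"],
                max_iter=config["rso"]["max_iter"],
                seed=seeds["tune"][k],
                bounds=space.bounds(),
            )
            hp, inner_err, _ = tune_bigru(
                train_ds, np.ones(masked.n_features, dtype=np.int8), space, rso_cfg, folds=inner_folds
            )
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"tuning stage failed on fold {k}: {exc}") from exc

        try:
            clf = BiGRUClassifier(
                hidden_size=hp["hidden_size"],
                learning_rate=hp["learning_rate"],
                epochs=hp["epochs"],
                batch_size=config["bigru"]["batch_size"],
                seed=seeds["train"][k],
            )
            clf.fit(masked.X[tr], masked.y[tr])
            preds = clf.predict(masked.X[te])
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"classification stage failed on fold {k}: {exc}") from exc

        rep = evaluate(preds, masked.y[te], masked.positive_label)
        fold_reports.append(rep.to_dict())
        fold_hps.append({**hp, "inner_cv_error": inner_err})
        total = rep if total is None else total + rep

    report = RunReport(
        config_hash=config.hash(),
        master_seed=config["seed"],
        n_features_total=dataset.n_features,
        fs=fs_result.to_dict() if fs_result is not None else None,
        fold_reports=fold_reports,
        fold_hyperparameters=fold_hps,
        aggregate=total.to_dict(),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        (out / "summary.txt").write_text(report.summary() + "\n")
    return report
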