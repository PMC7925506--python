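"""Trial file formats, run configuration and the end-to-end pipeline.

A trial on disk is a CSV with columns ``t, ax, ay, az, gx, gy, gz`` plus a
JSON sidecar (``<name>.json``) holding the label, the nominal sampling rate
and — for synthetic trials — the ground-truth contact times.  Configuration
round-trips through YAML or JSON with all seeds explicit.
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

from .benchmark import CVProtocol, benchmark_all, masks_table, results_table
from .classifiers import CLASSIFIER_NAMES
from .features import (
    FEATURE_NAMES,
    extract_features,
    features_to_matrix,
    normalize_features,
)
from .simulate import DEFAULT_RATE_POOL, RawTrial, generate_cohort

__all__ = ["TRIAL_COLUMNS", "RunConfig", "read_trial", "write_trial", "run_pipeline"]

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


@dataclass(frozen=True)
class RunConfig:
    """Every stage parameter of an end-to-end run, with stated defaults."""

    seed: int = 1
    # cohort
    n_healthy: int = 35
    n_pathological: int = 25
    rate_pool: tuple = DEFAULT_RATE_POOL
    duration_split: float = 41.0 / 60.0
    separation_scale: float = 1.0
    # preprocessing
    target_rate: float = 200.0
    wavelet: str = "sym4"
    levels: int = 4
    # valley detection
    search_frac: float = 0.3
    valley_stage: str = "filtered"
    # cross-validation
    test_size: int = 10
    repeats: int = 10
    classifiers: tuple = CLASSIFIER_NAMES

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rate_pool"] = list(self.rate_pool)
        d["classifiers"] = list(self.classifiers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "rate_pool" in d:
            d["rate_pool"] = tuple(float(r) for r in d["rate_pool"])
        if "classifiers" in d:
            d["classifiers"] = tuple(d["classifiers"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_trial(trial: RawTrial, path: str | Path) -> Path:
    """Write a trial CSV plus its JSON sidecar; returns the CSV path."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "t": trial.time,
            "ax": trial.accel[:, 0],
            "ay": trial.accel[:, 1],
            "az": trial.accel[:, 2],
            "gx": trial.gyro[:, 0],
            "gy": trial.gyro[:, 1],
            "gz": trial.gyro[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "label": trial.label,
        "sample_rate": trial.sample_rate,
        "trial_id": trial.trial_id,
    }
    if trial.truth_contacts is not None:
        sidecar["truth_contacts"] = [float(v) for v in trial.truth_contacts]
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_trial(path: str | Path) -> RawTrial:
    """Read a trial CSV (+ sidecar), validating uniform timestamps.

    The sampling rate is inferred from the timestamps and cross-checked
    against the sidecar within 1%.  Column order in the CSV is free as long
    as the header names match.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path.name} is missing columns: {missing}")
    t = df["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0 or np.any(dt <= 0):
        raise ValueError(f"trial file {path.name}: timestamps must strictly increase")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 0.01 * med:
        raise ValueError(
            f"trial file {path.name}: non-uniform timestamps (jitter beyond 1%)"
        )
    rate = 1.0 / med

    sidecar_path = path.with_suffix(".json")
    label, trial_id, truth = "unknown", path.stem, None
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        label = meta.get("label", label)
        trial_id = meta.get("trial_id", trial_id)
        if "truth_contacts" in meta:
            truth = np.asarray(meta["truth_contacts"], dtype=float)
        nominal = meta.get("sample_rate")
        if nominal is not None:
            if abs(rate - nominal) > 0.01 * nominal:
                raise ValueError(
                    f"trial file {path.name}: inferred rate {rate:.2f} Hz disagrees "
                    f"with sidecar rate {nominal:.2f} Hz by more than 1%"
                )
            rate = float(nominal)

    return RawTrial(
        time=t,
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        sample_rate=rate,
        label=label,
        trial_id=trial_id,
        truth_contacts=truth,
    )


def run_pipeline(
    config: RunConfig,
    in_dir: str | Path | None = None,
    out_dir: str | Path = "gaitbench_run",
) -> dict:
    """Execute the full flow: trials -> features -> normalization -> benchmark.

    Trials come from ``in_dir`` (every ``*.csv`` with the trial schema) or,
    when ``in_dir`` is None, from the seeded synthetic cohort described by
    ``config``.  Per-trial failures quarantine the trial; the run fails only
    if a class loses all its trials.  Outputs (features.csv, results.csv,
    masks.csv, config and report JSON) land in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if in_dir is None:
        trials = generate_cohort(
            n_healthy=config.n_healthy,
            n_pathological=config.n_pathological,
            rate_pool=config.rate_pool,
            duration_split=config.duration_split,
            seed=config.seed,
            separation_scale=config.separation_scale,
        )
    else:
        trials, quarantined_files = [], []
        for f in sorted(Path(in_dir).glob("*.csv")):
            if f.name == "features.csv":
                continue
            try:
                trials.append(read_trial(f))
            except Exception as exc:
                logger.warning("quarantined %s: %s", f.name, exc)
                quarantined_files.append((f.name, str(exc)))

    vectors, quarantined = [], []
    for trial in trials:
        try:
            vectors.append(
                extract_features(
                    trial,
                    target_rate=config.target_rate,
                    levels=config.levels,
                    search_frac=config.search_frac,
                    wavelet=config.wavelet,
                    valley_stage=config.valley_stage,
                )
            )
        except Exception as exc:
            logger.warning("quarantined trial %s: %s", trial.trial_id, exc)
            quarantined.append((trial.trial_id, str(exc)))
    if in_dir is not None:
        quarantined = quarantined_files + quarantined

    labels_present = {v.label for v in vectors}
    for cls in {t.label for t in trials}:
        if cls not in labels_present:
            raise RuntimeError(f"class {cls!r} lost all of its trials")

    fm = features_to_matrix(vectors)
    feat_df = pd.DataFrame(fm.X, columns=list(FEATURE_NAMES))
    feat_df.insert(0, "trial_id", fm.trial_ids)
    feat_df["label"] = fm.labels
    feat_df.to_csv(out_dir / "features.csv", index=False, float_format="%.9g")

    fm_norm = normalize_features(fm)
    protocol = CVProtocol(
        test_size=config.test_size, repeats=config.repeats, seed=config.seed
    )
    from .classifiers import default_specs

    specs = {n: s for n, s in default_specs().items() if n in config.classifiers}
    results = benchmark_all(fm_norm.X, fm_norm.labels, protocol, specs=specs)

    results_table(results).to_csv(out_dir / "results.csv", float_format="%.6f")
    masks_table(results).to_csv(out_dir / "masks.csv")
    config.save(out_dir / "config.json")

    report = {
        "config_hash": config.config_hash,
        "n_trials": len(trials),
        "n_processed": len(vectors),
        "n_quarantined": len(quarantined),
        "quarantined": quarantined,
        "results": {
            name: {
                "mean_accuracy_pct": r.mean_accuracy,
                "std_accuracy_pct": r.std_accuracy,
                "subset_mask": list(r.subset_mask),
                "n_features": r.n_features,
            }
            for name, r in results.items()
        },
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
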