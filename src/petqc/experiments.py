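"""Experiment sweeps over the synthetic cohort.

Three sweeps mirror the questions a transfer-learning study asks:

* **freeze_blocks** — clinical-score MAE as a function of how many of the
  five convolutional blocks are retrained on the scored data (0 = head
  only … 5 = everything), starting from a dose-inference pre-trained
  backbone;
* **n_patients** — performance as a function of how many scored patients
  enter the transfer-learning set (nested subsets, last two blocks
  retrained);
* **pipelines** — pre-training pipelines compared on a fixed test set
  (a @ 1e-3, a @ 1e-4, c by default; b/d are skipped with a logged notice
  when ImageNet weights are absent).

Every run's seed derives deterministically from the master seed, the sweep
level and the run index, so a whole sweep is reproducible from one
integer.  Test patients never enter any training or validation split.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .backbone import BackboneSpec, FreezePolicy, UnavailableResourceError
from .evaluation import evaluate_predictions
from .synthetic_data import AnatomyParams, PatientRecord, make_cohort
from .training import TrainConfig, run_pipeline

logger = logging.getLogger(__name__)

__all__ = [
    "SweepSpec",
    "ExperimentData",
    "make_experiment_data",
    "run_seed",
    "run_freeze_sweep",
    "run_patient_sweep",
    "run_pipeline_comparison",
    "dose_only_baseline",
    "load_config",
    "save_boxplot",
]

_LEVEL_KEYS = {"a": 10, "b": 11, "c": 12, "d": 13}


def run_seed(master_seed: int, level, run: int) -> int:
    """Deterministic per-run seed from (master seed, sweep level, run index)."""
    if isinstance(level, str):
        key = _LEVEL_KEYS.get(
            level, int(hashlib.sha256(level.encode()).hexdigest()[:8], 16)
        )
    else:
        key = int(level)
    return int(np.random.SeedSequence([master_seed, key, run]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: which knob, which levels, how many repeated runs."""

    kind: str  # freeze_blocks | n_patients | pipelines
    levels: tuple = ()
    n_runs: int = 5
    master_seed: int = 0
    config: TrainConfig = field(default_factory=TrainConfig)
    backbone: BackboneSpec = field(default_factory=lambda: BackboneSpec(base_width=4, input_size=32))
    per_plane: int = 10
    patch_size: int = 32

    def __post_init__(self):
        valid = {
            "freeze_blocks": set(range(6)),
            "n_patients": set(range(1, 8)),
            "pipelines": {"a", "a@1e-3", "a@1e-4", "b", "c", "d"},
        }
        if self.kind not in valid:
            raise ValueError(f"unknown sweep kind {self.kind!r}")
        if not set(self.levels) <= valid[self.kind]:
            raise ValueError(f"levels {self.levels} invalid for sweep {self.kind!r}")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(
            dict(
                kind=self.kind,
                levels=list(self.levels),
                n_runs=self.n_runs,
                master_seed=self.master_seed,
                lr=self.config.learning_rate,
                batch=self.config.batch_size,
                epochs=self.config.max_epochs,
                width=self.backbone.base_width,
                patch=self.patch_size,
                per_plane=self.per_plane,
            ),
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ExperimentData:
    """Fixed patient splits shared by every run of a sweep."""

    pretext: list[PatientRecord]  # 7-fraction patients for dose inference
    clinical_train: list[PatientRecord]
    clinical_val: list[PatientRecord]
    clinical_test: list[PatientRecord]


def make_experiment_data(
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 64, 48),
    n_pretext: int = 8,
    n_transfer: int = 7,
    n_val: int = 1,
    n_test: int = 3,
    anatomy: AnatomyParams | None = None,
) -> ExperimentData:
    """Build disjoint pretext / train / val / test phantom cohorts.

    Pretext patients carry all seven count fractions; clinical patients
    carry three (one per quality category), matching how reading sessions
    are shortened in practice.
    """
    ss = np.random.SeedSequence([seed, 77])
    s_pre, s_clin = (int(v) for v in ss.generate_state(2) % (2**31))
    pretext = make_cohort(
        n_pretext, fractions_per_patient=7, seed=s_pre, shape=shape, anatomy=anatomy, id_prefix="PTX"
    )
    clinical = make_cohort(
        n_transfer + n_val + n_test,
        fractions_per_patient=3,
        seed=s_clin,
        shape=shape,
        anatomy=anatomy,
        id_prefix="CLN",
    )
    return ExperimentData(
        pretext=pretext,
        clinical_train=clinical[:n_transfer],
        clinical_val=clinical[n_transfer : n_transfer + n_val],
        clinical_test=clinical[n_transfer + n_val :],
    )


def _rows_from_report(predictions: pd.DataFrame, base: dict) -> list[dict]:
    report = evaluate_predictions(predictions)
    rows = []
    for metric, vals in {**report.per_metric, "pooled": report.pooled}.items():
        rows.append({**base, "metric": metric, **vals})
    return rows


def _run_once(
    kind: str,
    data: ExperimentData,
    spec: SweepSpec,
    seed: int,
    freeze: FreezePolicy | None,
    train_subset: list[PatientRecord] | None = None,
    learning_rate: float | None = None,
) -> pd.DataFrame:
    t0 = time.perf_counter()
    config = replace(spec.config, seed=seed)
    if learning_rate is not None:
        config = replace(config, learning_rate=learning_rate)
    result = run_pipeline(
        kind,
        clinical_train=train_subset or data.clinical_train,
        clinical_val=data.clinical_val,
        clinical_test=data.clinical_test,
        pretext_cohort=data.pretext if kind in ("c", "d") else None,
        config=config,
        freeze=freeze,
        spec=spec.backbone,
        per_plane=spec.per_plane,
        patch_size=spec.patch_size,
    )
    logger.info(
        "pipeline %s seed %d finished in %.1fs (best epoch %d)",
        kind, seed, time.perf_counter() - t0, result.trained.best_epoch,
    )
    return result.predictions


def run_freeze_sweep(spec: SweepSpec, data: ExperimentData) -> pd.DataFrame:
    """Pipeline-c training at every freeze level k (retrain last k blocks)."""
    if len(data.clinical_train) < 3 or not data.clinical_val or not data.clinical_test:
        raise ValueError(
            "freeze sweep needs >= 3 training, >= 1 validation and >= 1 test patients"
        )
    rows = []
    for k in spec.levels:
        for run in range(spec.n_runs):
            seed = run_seed(spec.master_seed, int(k), run)
            preds = _run_once("c", data, spec, seed, FreezePolicy(int(k)))
            rows += _rows_from_report(
                preds,
                dict(level=int(k), run=run, seed=seed, config_hash=spec.config_hash,
                     split="test", sweep="freeze_blocks"),
            )
    return pd.DataFrame(rows)


def run_patient_sweep(spec: SweepSpec, data: ExperimentData) -> pd.DataFrame:
    """Transfer-set-size sweep with nested patient subsets, last 2 blocks retrained."""
    max_n = len(data.clinical_train)
    if any(int(n) > max_n for n in spec.levels):
        raise ValueError(f"sweep level exceeds transfer cohort size {max_n}")
    rows = []
    for n in spec.levels:
        subset = data.clinical_train[: int(n)]  # nested: n=1 ⊂ n=2 ⊂ …
        for run in range(spec.n_runs):
            seed = run_seed(spec.master_seed, int(n), run)
            preds = _run_once("c", data, spec, seed, FreezePolicy(2), train_subset=subset)
            rows += _rows_from_report(
                preds,
                dict(level=int(n), run=run, seed=seed, config_hash=spec.config_hash,
                     split="test", sweep="n_patients"),
            )
    return pd.DataFrame(rows)


def _parse_pipeline_level(level: str) -> tuple[str, float | None]:
    if "@" in level:
        kind, lr = level.split("@")
        return kind, float(lr)
    return level, None


def run_pipeline_comparison(spec: SweepSpec, data: ExperimentData) -> pd.DataFrame:
    """Compare pre-training pipelines on the fixed test patients."""
    rows = []
    for level in spec.levels:
        kind, lr = _parse_pipeline_level(level)
        for run in range(spec.n_runs):
            seed = run_seed(spec.master_seed, level, run)
            try:
                preds = _run_once(kind, data, spec, seed, None, learning_rate=lr)
            except UnavailableResourceError as err:
                logger.warning("pipeline %s skipped: %s", level, err)
                break
            rows += _rows_from_report(
                preds,
                dict(level=level, run=run, seed=seed, config_hash=spec.config_hash,
                     split="test", sweep="pipelines"),
            )
    return pd.DataFrame(rows)


def dose_only_baseline(
    train_records: list[PatientRecord], test_records: list[PatientRecord]
) -> pd.DataFrame:
    """Affine map from log10 weight-standardised dose to the three scores.

    A deliberately minimal reference model: it sees only the dose label,
    never the image, and serves as the floor any image-based model should
    beat on PR and DC.
    """
    def rows(records):
        out = []
        for rec in records:
            for df in rec.fractions:
                out.append(
                    dict(
                        patient_id=rec.patient_id,
                        fraction=df.fraction,
                        x=np.log10(df.fraction * rec.full_counts / rec.weight_kg),
                        **df.scores.as_dict(),
                    )
                )
        return pd.DataFrame(out)

    train_df, test_df = rows(train_records), rows(test_records)
    preds = []
    for metric in ("gqr", "pr", "dc"):
        coeffs = np.polyfit(train_df["x"], train_df[metric], deg=1)
        fitted = np.clip(np.polyval(coeffs, test_df["x"]), 0.0, 3.0)
        for (_, row), value in zip(test_df.iterrows(), fitted):
            preds.append(
                dict(
                    patient_id=row["patient_id"],
                    fraction=row["fraction"],
                    metric=metric.upper(),
                    predicted=float(value),
                    true=float(row[metric]),
                )
            )
    return pd.DataFrame(preds)


# ---------------------------------------------------------------------------
# Config + plotting
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML experiment config (synthetic / backbone / training / sweep blocks)."""
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_boxplot(table: pd.DataFrame, out_path: str | Path, value: str = "mae") -> Path:
    """Boxplot of a long-format sweep table (pooled rows), one box per level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pooled = table[table["metric"] == "pooled"]
    levels = list(dict.fromkeys(pooled["level"]))
    groups = [pooled.loc[pooled["level"] == lv, value].to_numpy() for lv in levels]
    fig, ax = plt.subplots(figsize=(1.2 * len(levels) + 2, 4))
    ax.boxplot(groups, tick_labels=[str(lv) for lv in levels])
    ax.set_xlabel("level")
    ax.set_ylabel(value)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
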