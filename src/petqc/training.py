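"""Optimisation protocol, dose-inference pretext pre-training and the
pre-training pipelines.

Training follows one fixed protocol: Adam, mean-squared-error loss,
batch size 10, with the checkpoint at the lowest validation loss kept.
Train and validation sets must be disjoint at the patient level — the
assertion runs before every fit.

Pipelines (by increasing amount of pre-training):

``a``  random initialisation, all blocks trainable, trained directly on
       the clinically scored patches (learning rate 1e-3 or 1e-4);
``b``  ImageNet-initialised backbone (requires locally available
       converted weights; absent weights are an explicit error);
``c``  dose-inference pretext pre-training from random initialisation:
       the backbone first regresses the weight-standardised dose from
       patches of an independent cohort, then its convolutional weights
       are fixed, the head is replaced with the three-output clinical
       head and (by default) only the head is trained;
``d``  as ``c`` but starting from ImageNet weights.

When the frozen prefix of the network reaches all the way to the first
trainable layer, its activations are precomputed once per dataset and
reused every epoch, which makes head-only transfer training fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._nn import Adam, mse_loss
from .backbone import (
    BackboneSpec,
    FreezePolicy,
    HeadSpec,
    QualityNet,
    UnavailableResourceError,
    apply_freeze,
    build_backbone,
    replace_head,
)
from .patch_pipeline import extract_patch_set, to_three_channel
from .synthetic_data import METRICS, PatientRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "LabelledPatches",
    "TrainedModel",
    "PretextResult",
    "train",
    "predict",
    "predictions_table",
    "cohort_patches",
    "pretext_target",
    "pretext_pretrain",
    "run_pipeline",
    "PipelineResult",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol (Adam + MSE, best-validation checkpointing)."""

    learning_rate: float = 1e-4
    batch_size: int = 10
    max_epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class LabelledPatches:
    """Patch pixel stack with regression targets and patient provenance."""

    x: np.ndarray  # (n, 3, size, size) float32
    y: np.ndarray  # (n, n_outputs) float32
    patient_ids: np.ndarray  # (n,) str
    fractions: np.ndarray  # (n,) float

    def __post_init__(self):
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")

    def __len__(self):
        return len(self.x)

    @property
    def patients(self) -> set[str]:
        return set(map(str, np.unique(self.patient_ids)))


@dataclass
class TrainedModel:
    model: QualityNet
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss
    best_epoch: int
    best_val_loss: float
    config: TrainConfig


@dataclass
class PretextResult:
    trained: TrainedModel
    target_min: float
    target_max: float
    val_mae: float
    val_exact_pct: float
    val_spearman: float


def _assert_disjoint_patients(groups: dict[str, set[str]]) -> None:
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlap = groups[a] & groups[b]
            if overlap:
                raise ValueError(
                    f"patient-level split violation: {sorted(overlap)} appear in both "
                    f"{a!r} and {b!r}"
                )


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _eval_loss(model: QualityNet, x: np.ndarray, y: np.ndarray, start: int, batch: int = 256) -> float:
    total, n = 0.0, 0
    for i in range(0, len(x), batch):
        pred = model.forward(x[i : i + batch], train=False, start=start)
        diff = pred - y[i : i + batch]
        total += float(np.sum(diff * diff))
        n += diff.size
    return total / n


def _precompute_stem(model: QualityNet, x: np.ndarray, stop: int, batch: int = 128) -> np.ndarray:
    if stop == 0:
        return x.astype(np.float32, copy=False)
    outs = []
    for i in range(0, len(x), batch):
        z = x[i : i + batch].astype(np.float32, copy=False)
        for layer in model.net.layers[:stop]:
            z = layer.forward(z, train=False)
        outs.append(z)
    return np.concatenate(outs, axis=0)


def train(
    model: QualityNet,
    train_patches: LabelledPatches,
    val_patches: LabelledPatches,
    config: TrainConfig,
) -> TrainedModel:
    """Fit ``model`` with Adam/MSE and return the lowest-validation-loss state.

    The activations of the frozen prefix (all layers below the first
    trainable one) are computed once per dataset and cached; optimisation
    then runs only on the trainable suffix.  Deterministic given
    ``config.seed`` and a fixed BLAS backend.
    """
    if len(train_patches) == 0 or len(val_patches) == 0:
        raise ValueError("train and validation sets must be non-empty")
    _assert_disjoint_patients(
        {"train": train_patches.patients, "val": val_patches.patients}
    )
    rng = np.random.default_rng(config.seed)
    stem_stop = model.first_trainable_layer()
    x_train = _precompute_stem(model, train_patches.x, stem_stop)
    x_val = _precompute_stem(model, val_patches.x, stem_stop)
    y_train = train_patches.y.astype(np.float32)
    y_val = val_patches.y.astype(np.float32)

    optimizer = Adam(model.net.trainable_params(), lr=config.learning_rate)
    history = []
    best_val = np.inf
    best_epoch = -1
    best_state = {k: v.copy() for k, v in model.net.trainable_params().items()}

    for epoch in range(config.max_epochs):
        train_loss, n_batches = 0.0, 0
        for idx in _iter_batches(len(x_train), config.batch_size, rng):
            pred = model.forward(x_train[idx], train=True, start=stem_stop)
            loss, dpred = mse_loss(pred, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; lower the learning rate"
                )
            model.net.backward(dpred, stop_at=stem_stop)
            optimizer.step(model.net.trainable_grads())
            train_loss += loss
            n_batches += 1
        val_loss = _eval_loss(model, x_val, y_val, stem_stop)
        history.append(
            dict(epoch=epoch, train_loss=train_loss / max(n_batches, 1), val_loss=val_loss)
        )
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.net.trainable_params().items()}

    model.net.set_params(best_state)
    return TrainedModel(
        model=model,
        history=pd.DataFrame(history),
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
        config=config,
    )


def predict(model: QualityNet, patches: LabelledPatches, batch_size: int = 256) -> np.ndarray:
    return model.predict(patches.x, batch_size=batch_size)


# ---------------------------------------------------------------------------
# Patch dataset assembly from cohorts
# ---------------------------------------------------------------------------


def pretext_target(fraction: float, full_counts: int, weight_kg: float) -> float:
    """Weight-standardised dose: the pretext regression label."""
    return fraction * full_counts / weight_kg


def cohort_patches(
    records: list[PatientRecord],
    per_plane: int = 10,
    size: int = 32,
    seed: int = 0,
    target: str = "clinical",
) -> LabelledPatches:
    """Extract a plane-balanced patch dataset from every volume of a cohort.

    ``target='clinical'`` attaches the (GQR, PR, DC) triple of the source
    reconstruction; ``target='dose'`` attaches the raw weight-standardised
    dose (rescale it before regression).  Patch locations are drawn
    independently per volume.
    """
    xs, ys, pids, fracs = [], [], [], []
    ss = np.random.SeedSequence(seed)
    for rec, child in zip(records, ss.spawn(len(records))):
        vol_seeds = child.generate_state(len(rec.fractions)) % (2**31)
        for df, vseed in zip(rec.fractions, vol_seeds):
            pset = extract_patch_set(
                df.volume,
                per_plane=per_plane,
                size=size,
                seed=int(vseed),
                patient_id=rec.patient_id,
                fraction=df.fraction,
            )
            for patch in pset.patches:
                xs.append(to_three_channel(patch))
                if target == "clinical":
                    ys.append([df.scores.gqr, df.scores.pr, df.scores.dc])
                elif target == "dose":
                    ys.append([pretext_target(df.fraction, rec.full_counts, rec.weight_kg)])
                else:
                    raise ValueError(f"unknown target {target!r}")
                pids.append(rec.patient_id)
                fracs.append(df.fraction)
    return LabelledPatches(
        x=np.asarray(xs, dtype=np.float32),
        y=np.asarray(ys, dtype=np.float32),
        patient_ids=np.asarray(pids),
        fractions=np.asarray(fracs, dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# Pretext pre-training: dose inference
# ---------------------------------------------------------------------------


def pretext_pretrain(
    cohort: list[PatientRecord],
    config: TrainConfig,
    val_patient: PatientRecord,
    spec: BackboneSpec | None = None,
    per_plane: int = 10,
    patch_size: int = 32,
    init: str = "random",
    imagenet_weights=None,
    target_scale: str = "log-minmax",
) -> PretextResult:
    """Pre-train a dose-head backbone to regress standardised dose from patches.

    The weight-standardised dose spans more than two decades across the
    seven count fractions, so by default it is log10-transformed before
    min–max rescaling to [0, 1] over the training cohort
    (``target_scale='log-minmax'``); ``'minmax'`` rescales the raw dose.
    The held-out validation patient is reported as MAE on the unit-scaled
    target, percentage exact agreement after nearest-discrete-level
    assignment of per-volume mean predictions, and Spearman rank
    correlation between the per-volume mean prediction and the true count
    fraction.
    """
    if any(rec.patient_id == val_patient.patient_id for rec in cohort):
        raise ValueError("validation patient must not be part of the pretext cohort")
    if target_scale not in ("log-minmax", "minmax"):
        raise ValueError(f"unknown target_scale {target_scale!r}")
    spec = spec or BackboneSpec(input_size=patch_size)
    ss = np.random.SeedSequence(config.seed)
    s_model, s_train, s_val = (int(v) for v in ss.generate_state(3) % (2**31))

    train_set = cohort_patches(cohort, per_plane, patch_size, seed=s_train, target="dose")
    val_set = cohort_patches([val_patient], per_plane, patch_size, seed=s_val, target="dose")

    transform = np.log10 if target_scale == "log-minmax" else np.asarray
    y_train_raw = transform(train_set.y)
    y_val_raw = transform(val_set.y)
    t_min = float(y_train_raw.min())
    t_max = float(y_train_raw.max())
    span = max(t_max - t_min, 1e-12)
    train_scaled = replace_targets(train_set, (y_train_raw - t_min) / span)
    val_scaled = replace_targets(val_set, (y_val_raw - t_min) / span)

    model = build_backbone(
        spec, HeadSpec(kind="dose"), init=init, seed=s_model, imagenet_weights=imagenet_weights
    )
    trained = train(model, train_scaled, val_scaled, config)

    preds = predict(trained.model, val_scaled)[:, 0]
    truth = val_scaled.y[:, 0]
    val_mae = float(np.mean(np.abs(preds - truth)))
    # exact agreement at reconstruction level: per-volume mean prediction
    # assigned to the nearest of the discrete training target levels
    per_vol = (
        pd.DataFrame(dict(fraction=val_scaled.fractions, pred=preds, true=truth))
        .groupby("fraction", sort=True)
        .mean()
    )
    levels = np.unique(train_scaled.y[:, 0])
    vol_pred = per_vol["pred"].to_numpy()
    vol_true = per_vol["true"].to_numpy()
    nearest = levels[np.argmin(np.abs(vol_pred[:, None] - levels[None, :]), axis=1)]
    true_level = levels[np.argmin(np.abs(vol_true[:, None] - levels[None, :]), axis=1)]
    exact_pct = 100.0 * float(np.mean(nearest == true_level))

    from scipy.stats import spearmanr

    rho = float(spearmanr(per_vol.index.to_numpy(), vol_pred).statistic)
    return PretextResult(
        trained=trained,
        target_min=t_min,
        target_max=t_max,
        val_mae=val_mae,
        val_exact_pct=exact_pct,
        val_spearman=rho,
    )


def replace_targets(patches: LabelledPatches, y: np.ndarray) -> LabelledPatches:
    return LabelledPatches(
        x=patches.x,
        y=np.asarray(y, dtype=np.float32),
        patient_ids=patches.patient_ids,
        fractions=patches.fractions,
    )


# ---------------------------------------------------------------------------
# Pre-training pipelines
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    kind: str
    trained: TrainedModel
    predictions: pd.DataFrame  # patient_id, fraction, metric, predicted, true
    pretext: PretextResult | None = None


def predictions_table(
    model: QualityNet,
    patches: LabelledPatches,
    per_image: bool = True,
    clip: tuple[float, float] = (0.0, 3.0),
) -> pd.DataFrame:
    """Prediction table for a clinical-head model.

    With ``per_image=True`` (default) patch predictions are averaged to
    one clipped score per reconstruction and metric; otherwise every
    patch contributes its own clipped row.
    """
    raw = predict(model, patches)
    frame = pd.DataFrame(
        dict(patient_id=patches.patient_ids, fraction=patches.fractions)
    )
    rows = []
    for m_idx, metric in enumerate(METRICS):
        frame["pred"] = raw[:, m_idx]
        frame["true"] = patches.y[:, m_idx]
        if per_image:
            grouped = frame.groupby(["patient_id", "fraction"], sort=True).agg(
                predicted=("pred", "mean"), true=("true", "first")
            )
            pairs = ((pid, frac, row["predicted"], row["true"]) for (pid, frac), row in grouped.iterrows())
        else:
            pairs = (
                (row["patient_id"], row["fraction"], row["pred"], row["true"])
                for _, row in frame.iterrows()
            )
        for pid, frac, pred, true in pairs:
            rows.append(
                dict(
                    patient_id=pid,
                    fraction=frac,
                    metric=metric.upper(),
                    predicted=float(np.clip(pred, *clip)),
                    true=float(true),
                )
            )
    return pd.DataFrame(rows)


def run_pipeline(
    kind: str,
    clinical_train: list[PatientRecord],
    clinical_val: list[PatientRecord],
    clinical_test: list[PatientRecord],
    pretext_cohort: list[PatientRecord] | None = None,
    config: TrainConfig | None = None,
    freeze: FreezePolicy | None = None,
    spec: BackboneSpec | None = None,
    per_plane: int = 10,
    patch_size: int = 32,
    imagenet_weights=None,
    pretext_config: TrainConfig | None = None,
    per_image: bool = True,
) -> PipelineResult:
    """Run one pre-training pipeline end to end and evaluate on test patients.

    Patient-level split hygiene across {pretext, train, val, test} is
    asserted up front.  For pipelines c/d the pretext cohort's last
    patient is held out as the pretext validation patient; the default
    freeze for the clinical stage is fully fixed convolutions (head only),
    configurable via ``freeze``.  ``pretext_config`` controls the pretext
    stage independently; by default it mirrors ``config`` but at the
    protocol's default learning rate of 1e-4, so a clinical-stage
    learning-rate variant does not leak into pre-training.
    """
    if kind not in ("a", "b", "c", "d"):
        raise ValueError(f"unknown pipeline {kind!r}")
    if not clinical_train:
        raise ValueError("clinical training cohort is empty")
    config = config or TrainConfig()
    spec = spec or BackboneSpec(input_size=patch_size)

    groups = {
        "clinical_train": {r.patient_id for r in clinical_train},
        "clinical_val": {r.patient_id for r in clinical_val},
        "clinical_test": {r.patient_id for r in clinical_test},
    }
    if pretext_cohort:
        groups["pretext"] = {r.patient_id for r in pretext_cohort}
    _assert_disjoint_patients(groups)

    ss = np.random.SeedSequence(config.seed)
    seeds = [int(v) for v in ss.generate_state(6) % (2**31)]

    pretext_result = None
    if kind == "a":
        model = build_backbone(spec, HeadSpec(kind="clinical"), init="random", seed=seeds[0])
        model = apply_freeze(model, freeze or FreezePolicy(5))
    elif kind == "b":
        model = build_backbone(
            spec,
            HeadSpec(kind="clinical"),
            init="imagenet",
            seed=seeds[0],
            imagenet_weights=imagenet_weights,
        )
        model = apply_freeze(model, freeze or FreezePolicy(2))
    else:  # c / d
        if not pretext_cohort or len(pretext_cohort) < 2:
            raise ValueError("pipelines c/d require a pretext cohort of >= 2 patients")
        pre_cfg = replace(pretext_config or replace(config, learning_rate=1e-4), seed=seeds[1])
        pretext_result = pretext_pretrain(
            pretext_cohort[:-1],
            pre_cfg,
            val_patient=pretext_cohort[-1],
            spec=spec,
            per_plane=per_plane,
            patch_size=patch_size,
            init="random" if kind == "c" else "imagenet",
            imagenet_weights=imagenet_weights,
        )
        model = replace_head(
            pretext_result.trained.model, HeadSpec(kind="clinical"), seed=seeds[2]
        )
        # conv weights fixed by default: only the replacement head trains
        model = apply_freeze(model, freeze or FreezePolicy(0))

    train_set = cohort_patches(clinical_train, per_plane, patch_size, seed=seeds[3])
    val_set = cohort_patches(clinical_val, per_plane, patch_size, seed=seeds[4])
    test_set = cohort_patches(clinical_test, per_plane, patch_size, seed=seeds[5])

    trained = train(model, train_set, val_set, config)
    predictions = predictions_table(trained.model, test_set, per_image=per_image)
    return PipelineResult(kind=kind, trained=trained, predictions=predictions, pretext=pretext_result)
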