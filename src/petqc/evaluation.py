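"""Agreement metrics between predicted and clinician-assigned quality scores.

Clinician scores live on a 0–3 scale in 0.5 steps.  Four metrics are
computed per clinical metric (GQR, PR, DC) and pooled:

* **MAE** — mean absolute error on the *unrounded* regression output;
* **% exact agreement** — prediction equals the clinician score after
  rounding to the 0.5 grid (halves round up);
* **% close agreement** — rounded prediction within ±0.5 of the score;
* **Spearman rank correlation** — average ranks on ties; undefined (NaN)
  when either side has zero variance, never silently zero.

Patch-level predictions are aggregated to one score per reconstructed
image by averaging and clipping to [0, 3] before the metrics are applied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "round_to_half",
    "aggregate_patient_score",
    "mae",
    "exact_agreement",
    "close_agreement",
    "spearman",
    "EvalReport",
    "evaluate_predictions",
]

_EPS = 1e-9


def round_to_half(x):
    """Round to the nearest multiple of 0.5; exact quarter values round up."""
    return np.floor(np.asarray(x, dtype=np.float64) * 2.0 + 0.5) / 2.0


def aggregate_patient_score(patch_predictions) -> float:
    """Mean of a reconstruction's patch predictions, clipped to [0, 3]."""
    arr = np.asarray(patch_predictions, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty prediction list")
    return float(np.clip(arr.mean(), 0.0, 3.0))


def _as_pairs(predicted, true) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=np.float64).ravel()
    t = np.asarray(true, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("metric requires at least one (predicted, true) pair")
    if p.shape != t.shape:
        raise ValueError("predicted and true must have equal length")
    return p, t


def mae(predicted, true) -> float:
    """Mean absolute error on unrounded predictions."""
    p, t = _as_pairs(predicted, true)
    return float(np.mean(np.abs(p - t)))


def exact_agreement(predicted, true) -> float:
    """Percentage of pairs whose grid-rounded prediction equals the score."""
    p, t = _as_pairs(predicted, true)
    return 100.0 * float(np.mean(np.abs(round_to_half(p) - t) < _EPS))


def close_agreement(predicted, true) -> float:
    """Percentage of pairs whose grid-rounded prediction is within ±0.5."""
    p, t = _as_pairs(predicted, true)
    return 100.0 * float(np.mean(np.abs(round_to_half(p) - t) <= 0.5 + _EPS))


def spearman(predicted, true) -> float:
    """Spearman rank correlation (average ranks on ties); NaN if degenerate."""
    p, t = _as_pairs(predicted, true)
    if p.size < 2:
        raise ValueError("spearman requires at least two pairs")
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        warnings.warn("spearman undefined: zero variance in one variable", stacklevel=2)
        return float("nan")
    return float(spearmanr(p, t).statistic)


@dataclass
class EvalReport:
    """Per-metric and pooled agreement statistics for one evaluation run."""

    per_metric: dict[str, dict[str, float]]
    pooled: dict[str, float]
    n_pairs: int
    seeds: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            dict(per_metric=self.per_metric, pooled=self.pooled, n_pairs=self.n_pairs, seeds=self.seeds),
            indent=2,
            allow_nan=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(metric="pooled", **self.pooled)]
        rows += [dict(metric=m, **vals) for m, vals in self.per_metric.items()]
        return pd.DataFrame(rows)


def _metric_block(predicted, true) -> dict[str, float]:
    return dict(
        mae=mae(predicted, true),
        exact_pct=exact_agreement(predicted, true),
        close_pct=close_agreement(predicted, true),
        spearman=spearman(predicted, true) if len(np.atleast_1d(predicted)) >= 2 else float("nan"),
    )


def evaluate_predictions(predictions: pd.DataFrame, seeds: list[int] | None = None) -> EvalReport:
    """Score a predictions table (patient_id, fraction, metric, predicted, true).

    Rows are expected at image level (one row per reconstruction and
    clinical metric); metrics are computed per clinical metric and pooled
    across all of them.
    """
    required = {"metric", "predicted", "true"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"predictions table lacks columns {sorted(missing)}")
    per_metric = {}
    for metric, group in predictions.groupby("metric", sort=True):
        per_metric[str(metric)] = _metric_block(
            group["predicted"].to_numpy(), group["true"].to_numpy()
        )
    pooled = _metric_block(predictions["predicted"].to_numpy(), predictions["true"].to_numpy())
    return EvalReport(
        per_metric=per_metric,
        pooled=pooled,
        n_pairs=len(predictions),
        seeds=list(seeds or []),
    )
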