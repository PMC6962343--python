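"""Evaluation battery for continuous binding-affinity predictions.

Four statistics are computed on a set of (predicted, measured) pairs:

* **MSE** — mean squared error, (1/n) sum (p_k - y_k)^2.
* **CI** — concordance index: over every pair of examples whose measured
  affinities are strictly ordered (delta_x > delta_y), the step function
  h(b_x - b_y) scores 1 for a correctly ordered prediction pair, 0.5 for a
  tie and 0 for an inversion; CI is the normalised sum. Ties in the measured
  values are excluded from the normaliser Z.
* **rm2** — external-validation metric r^2 * (1 - sqrt(r^2 - r0^2)), where
  r^2 is the squared Pearson correlation of predictions and observations and
  r0^2 the squared correlation of the least-squares fit through the origin;
  values above 0.5 conventionally indicate an acceptable model.
* **AUPR** — area under the precision-recall curve (average-precision
  estimator) after binarising affinities at a modality-appropriate threshold
  (pKd 7 for Davis-style dissociation data, 12.1 for KIBA scores).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

#: conventional binder/non-binder thresholds
DAVIS_PKD_THRESHOLD = 7.0
KIBA_THRESHOLD = 12.1


@dataclass(frozen=True)
class PredictionSet:
    """Aligned vectors of predicted and measured affinities."""

    predictions: np.ndarray
    truths: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.predictions, dtype=np.float64)
        y = np.asarray(self.truths, dtype=np.float64)
        if p.shape != y.shape or p.ndim != 1:
            raise ValueError("predictions and truths must be equal-length vectors")
        if p.size < 1:
            raise ValueError("need at least one prediction")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(y))):
            raise ValueError("predictions and truths must be finite")
        object.__setattr__(self, "predictions", p)
        object.__setattr__(self, "truths", y)

    @property
    def n(self) -> int:
        return int(self.predictions.size)


@dataclass(frozen=True)
class CorrelationPair:
    r2: float   # squared Pearson correlation (fit with intercept)
    r02: float  # squared correlation of the through-origin fit


@dataclass(frozen=True)
class BinaryLabeledScores:
    scores: np.ndarray
    labels: np.ndarray
    threshold_used: float


def step_function(m):
    """h(m) = 1 if m > 0, 0.5 if m == 0, 0 if m < 0 (elementwise)."""
    m = np.asarray(m, dtype=np.float64)
    out = np.where(m > 0, 1.0, np.where(m < 0, 0.0, 0.5))
    return float(out) if out.ndim == 0 else out


def mse(ps: PredictionSet) -> float:
    """Mean squared error between predictions and measured values."""
    return float(np.mean((ps.predictions - ps.truths) ** 2))


def concordance_index(ps: PredictionSet) -> float:
    """CI = (1/Z) sum_{delta_x > delta_y} h(b_x - b_y), Z = #{strictly
    ordered truth pairs}. Vectorised over all O(n^2) pairs."""
    if ps.n < 2:
        raise ValueError("CI needs at least 2 predictions")
    y, p = ps.truths, ps.predictions
    dy = y[:, None] - y[None, :]
    ordered = dy > 0  # row truth strictly larger than column truth
    z = int(ordered.sum())
    if z == 0:
        raise ValueError("CI undefined (Z=0): all measured values equal")
    dp = p[:, None] - p[None, :]
    return float(np.sum(step_function(dp)[ordered]) / z)


def squared_correlations(ps: PredictionSet) -> CorrelationPair:
    """r^2 (with intercept) and r0^2 (through-origin fit of observations on
    predictions): r0^2 = 1 - sum (y - k p)^2 / sum (y - mean y)^2 with
    k = sum(p y) / sum(p^2)."""
    if ps.n < 3:
        raise ValueError("need at least 3 points for squared correlations")
    p, y = ps.predictions, ps.truths
    if np.var(p) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlations undefined")
    r = stats.pearsonr(p, y).statistic
    k = float(np.sum(p * y) / np.sum(p * p))
    ss_res = float(np.sum((y - k * p) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return CorrelationPair(r2=float(r * r), r02=1.0 - ss_res / ss_tot)


def rm2_index(cp: CorrelationPair) -> float:
    """rm2 = r^2 (1 - sqrt(r^2 - r0^2)); the radicand is clamped at 0 when
    r0^2 exceeds r^2 numerically, keeping the metric real-valued."""
    radicand = max(cp.r2 - cp.r02, 0.0)
    return float(cp.r2 * (1.0 - np.sqrt(radicand)))


def binarize_affinities(affinities, threshold: float) -> np.ndarray:
    """Label 1 (binder) iff affinity >= threshold, else 0."""
    a = np.asarray(affinities, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("affinities must be finite")
    return (a >= threshold).astype(np.int64)


def aupr(bs: BinaryLabeledScores) -> float:
    """Average precision: mean over positives of the precision at their rank,
    with a stable descending-score sort (score ties broken by original
    index). Requires both classes."""
    scores = np.asarray(bs.scores, dtype=np.float64)
    labels = np.asarray(bs.labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("AUPR undefined: need both a positive and a negative label")
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    tp = np.cumsum(ranked)
    precision_at_rank = tp / np.arange(1, labels.size + 1)
    return float(precision_at_rank[ranked == 1].sum() / n_pos)


def metric_report(ps: PredictionSet, threshold: float | None = None) -> dict:
    """Full battery as one flat dict; AUPR is recorded as unavailable (with
    the reason) when binarisation leaves a single class."""
    report: dict = {"n": ps.n, "mse": mse(ps), "ci": concordance_index(ps)}
    report["rm2"] = rm2_index(squared_correlations(ps))
    report["threshold"] = threshold
    if threshold is None:
        report["aupr"] = None
        report["aupr_unavailable_reason"] = "no binarization threshold supplied"
    else:
        labels = binarize_affinities(ps.truths, threshold)
        try:
            report["aupr"] = aupr(BinaryLabeledScores(ps.predictions, labels, threshold))
        except ValueError as exc:
            report["aupr"] = None
            report["aupr_unavailable_reason"] = str(exc)
    return report


def write_metric_report(report: dict, json_path: str | Path | None = None,
                        tsv_path: str | Path | None = None) -> None:
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report, indent=2) + "\n")
    if tsv_path is not None:
        keys = [k for k in ("ci", "mse", "rm2", "aupr", "n", "threshold") if k in report]
        with open(tsv_path, "w") as fh:
            fh.write("\t".join(keys) + "\n")
            fh.write("\t".join(str(report[k]) for k in keys) + "\n")
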