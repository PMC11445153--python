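"""Uncertainty-aware evaluation metrics for binary (one-vs-all) classifiers.

This module contains the metric mathematics used throughout the package:

* predictive mean and predictive entropy of a set of stochastic forward
  passes (Monte Carlo dropout, deep ensembles, Bayesian weight sampling);
* certainty partitioning of test instances by thresholding the normalized
  predictive entropy;
* the uncertainty confusion matrix — the 2x2 cross of prediction
  *correctness* (correct / incorrect) and *certainty* (certain / uncertain)
  with cells TC (correct & certain), TU (incorrect & uncertain),
  FC (incorrect & certain) and FU (correct & uncertain) — and the
  uncertainty-aware metrics UAcc, USen, USpe, UPre, UF1 derived from it;
* the traditional confusion matrix and its metrics;
* calibration metrics: expected calibration error (ECE) over equal-width
  confidence bins, and the Brier score;
* AUC-ROC;
* the "percentage uncertainty" delta between a traditional metric and its
  uncertainty-aware counterpart, both on the 0-100 scale.

Entropies are measured in nats.  Thresholding always uses the entropy
normalized by ln(C) (C = number of classes, 2 for a one-vs-all task) so a
threshold such as 0.30 is scale-free in the class count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


class InvalidInputError(ValueError):
    """Inputs violate a structural precondition (shape, length, emptiness)."""


class InvalidParameterError(ValueError):
    """A tuning parameter (threshold, bin count) is out of its domain."""


class InvalidDistributionError(ValueError):
    """A probability vector has negative mass or does not sum to one."""


class UndefinedAUCError(ValueError):
    """AUC-ROC is undefined because only one class is present."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbabilitySample:
    """Positive-class probabilities from T stochastic forward passes.

    ``probs`` has shape (T, n): row t holds the probabilities assigned to the
    positive class by the t-th stochastic realization of the predictor
    (a dropout mask, an ensemble member, or a weight draw) for each of the
    n instances.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 1:
            raise InvalidInputError(
                f"probs must be a (T, n) matrix with T >= 1 and n >= 1, got shape {p.shape}"
            )
        if np.any(~np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
            raise InvalidInputError("probabilities must be finite and in [0, 1]")
        object.__setattr__(self, "probs", p)

    @property
    def n_passes(self) -> int:
        return self.probs.shape[0]

    @property
    def n_instances(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class PredictiveSummary:
    """Per-instance summary of a ProbabilitySample at a certainty threshold."""

    mu_pred: np.ndarray        # mean positive-class probability, in [0, 1]
    entropy: np.ndarray        # predictive entropy of (mu, 1-mu), nats
    entropy_norm: np.ndarray   # entropy / ln(2), in [0, 1]
    predicted_label: np.ndarray  # 1 iff mu_pred >= 0.5
    certain: np.ndarray        # certain iff entropy_norm <= threshold
    threshold: float


@dataclass(frozen=True)
class UncertaintyConfusionMatrix:
    """Counts of the correctness x certainty cross-classification."""

    TC: int  # correct and certain
    TU: int  # incorrect and uncertain
    FC: int  # incorrect and certain
    FU: int  # correct and uncertain

    def __post_init__(self) -> None:
        if min(self.TC, self.TU, self.FC, self.FU) < 0:
            raise InvalidInputError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TC + self.TU + self.FC + self.FU


@dataclass(frozen=True)
class BinaryConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise InvalidInputError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class UncertaintyMetrics:
    """USen, USpe, UPre, UAcc, UF1; 0/0 ratios are 0 and flagged degenerate."""

    u_sens: float
    u_spec: float
    u_prec: float
    u_acc: float
    u_f1: float
    degenerate: tuple[str, ...] = ()


@dataclass(frozen=True)
class TraditionalMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    degenerate: tuple[str, ...] = ()


@dataclass
class MetricReport:
    """All metric values for one one-vs-all task evaluated with one technique.

    Values are stored as fractions in [0, 1] (ece and brier on their natural
    scales); output writers convert to the percent scale.
    """

    task: int | str
    technique: str
    threshold: float
    accuracy: float
    f1: float
    precision: float
    sensitivity: float
    specificity: float
    auc_roc: float
    u_acc: float
    u_f1: float
    u_prec: float
    u_sens: float
    u_spec: float
    u_auc_roc: float
    ece: float
    brier: float
    degenerate: tuple[str, ...] = ()

    _METRIC_FIELDS = (
        "accuracy", "f1", "precision", "sensitivity", "specificity", "auc_roc",
        "u_acc", "u_f1", "u_prec", "u_sens", "u_spec", "u_auc_roc", "ece", "brier",
    )

    def as_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "degenerate"}
        out["degenerate"] = ";".join(self.degenerate)
        return out


# ---------------------------------------------------------------------------
# predictive mean and entropy
# ---------------------------------------------------------------------------


def predictive_mean(samples: ProbabilitySample) -> np.ndarray:
    """Element-wise mean of the positive-class probability over the T passes."""
    return samples.probs.mean(axis=0)


def predictive_entropy(p: np.ndarray) -> np.ndarray | float:
    """Entropy -sum_c p_c ln p_c (nats) of one or many distributions.

    ``p`` is a length-C probability vector, or an (n, C) matrix of row
    distributions.  0 * ln 0 is taken as 0.  Rows must be non-negative and
    sum to 1 within 1e-8.
    """
    arr = np.asarray(p, dtype=float)
    scalar = arr.ndim == 1
    rows = arr[None, :] if scalar else arr
    if rows.ndim != 2 or rows.shape[1] < 1:
        raise InvalidDistributionError(f"expected a distribution or matrix of rows, got shape {arr.shape}")
    if np.any(rows < 0):
        raise InvalidDistributionError("probabilities must be non-negative")
    sums = rows.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-8):
        raise InvalidDistributionError("each distribution must sum to 1 within 1e-8")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(rows > 0, rows * np.log(rows), 0.0)
    ent = -terms.sum(axis=1)
    ent = np.maximum(ent, 0.0)  # clip -0.0 from rounding
    return float(ent[0]) if scalar else ent


def binary_entropy(mu: np.ndarray) -> np.ndarray:
    """Predictive entropy of the two-class distribution (mu, 1-mu), in nats."""
    mu = np.asarray(mu, dtype=float)
    return predictive_entropy(np.column_stack([mu, 1.0 - mu]))


def partition_certainty(entropy_norm: np.ndarray, threshold: float) -> np.ndarray:
    """Certainty flags: an instance is *uncertain* iff entropy_norm > threshold.

    Boundary instances (entropy_norm == threshold) count as certain.
    """
    if not (0.0 <= threshold <= 1.0):
        raise InvalidParameterError(f"threshold must be in [0, 1], got {threshold}")
    return np.asarray(entropy_norm, dtype=float) <= threshold


def summarize(samples: ProbabilitySample, threshold: float = 0.3) -> PredictiveSummary:
    """Reduce per-pass probabilities to per-instance predictions and certainty.

    The predicted label is 1 iff the predictive mean is >= 0.5 (ties go to
    the positive class); certainty comes from the ln(2)-normalized entropy
    of the mean binary distribution.
    """
    mu = predictive_mean(samples)
    ent = binary_entropy(mu)
    ent_norm = ent / np.log(2.0)
    return PredictiveSummary(
        mu_pred=mu,
        entropy=ent,
        entropy_norm=ent_norm,
        predicted_label=(mu >= 0.5).astype(int),
        certain=partition_certainty(ent_norm, threshold),
        threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# confusion matrices
# ---------------------------------------------------------------------------


def _check_aligned(*arrays) -> tuple[np.ndarray, ...]:
    out = [np.asarray(a) for a in arrays]
    n = out[0].shape[0] if out[0].ndim else -1
    for a in out:
        if a.ndim != 1 or a.shape[0] != n:
            raise InvalidInputError("inputs must be 1-D arrays of equal length")
    if n < 1:
        raise InvalidInputError("inputs must be non-empty")
    return tuple(out)


def binary_confusion(predicted: np.ndarray, truth: np.ndarray) -> BinaryConfusionMatrix:
    predicted, truth = _check_aligned(predicted, truth)
    pred = predicted.astype(bool)
    pos = truth.astype(bool)
    return BinaryConfusionMatrix(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def uncertainty_confusion(
    predicted: np.ndarray, truth: np.ndarray, certain: np.ndarray
) -> UncertaintyConfusionMatrix:
    """Tally the correctness x certainty cross-classification."""
    predicted, truth, certain = _check_aligned(predicted, truth, certain)
    correct = np.asarray(predicted) == np.asarray(truth)
    certain = certain.astype(bool)
    return UncertaintyConfusionMatrix(
        TC=int(np.sum(correct & certain)),
        TU=int(np.sum(~correct & ~certain)),
        FC=int(np.sum(~correct & certain)),
        FU=int(np.sum(correct & ~certain)),
    )


def _ratio(num: float, den: float, name: str, degenerate: list[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def u_metrics(cm: UncertaintyConfusionMatrix) -> UncertaintyMetrics:
    """Uncertainty-aware metrics from the uncertainty confusion matrix.

    USen = TU/(TU+FC) rewards flagging wrong predictions as uncertain;
    USpe = TC/(TC+FU) rewards confidence in correct ones; UAcc = (TC+TU)/n
    is the rate of desirable outcomes; UF1 is the harmonic mean of UPre and
    USen.  A 0/0 ratio yields 0 and the metric name is flagged degenerate.
    """
    if cm.n < 1:
        raise InvalidInputError("empty confusion matrix")
    deg: list[str] = []
    u_sens = _ratio(cm.TU, cm.TU + cm.FC, "u_sens", deg)
    u_spec = _ratio(cm.TC, cm.TC + cm.FU, "u_spec", deg)
    u_prec = _ratio(cm.TU, cm.TU + cm.FU, "u_prec", deg)
    u_acc = (cm.TU + cm.TC) / cm.n
    u_f1 = _ratio(2.0 * u_prec * u_sens, u_prec + u_sens, "u_f1", deg)
    return UncertaintyMetrics(u_sens, u_spec, u_prec, u_acc, u_f1, tuple(deg))


def traditional_metrics(cm: BinaryConfusionMatrix) -> TraditionalMetrics:
    """Sensitivity, specificity, accuracy, precision and F1 from TP/TN/FP/FN."""
    if cm.n < 1:
        raise InvalidInputError("empty confusion matrix")
    deg: list[str] = []
    sens = _ratio(cm.TP, cm.TP + cm.FN, "sensitivity", deg)
    spec = _ratio(cm.TN, cm.TN + cm.FP, "specificity", deg)
    prec = _ratio(cm.TP, cm.TP + cm.FP, "precision", deg)
    acc = (cm.TP + cm.TN) / cm.n
    f1 = _ratio(2.0 * prec * sens, prec + sens, "f1", deg)
    return TraditionalMetrics(sens, spec, acc, prec, f1, tuple(deg))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def ece(
    mu_pred: np.ndarray, truth: np.ndarray, n_bins: int = 10
) -> tuple[float, pd.DataFrame]:
    """Expected calibration error over equal-width confidence bins.

    Confidence of an instance is max(mu, 1-mu), the probability assigned to
    the predicted label; an instance is correct when that label matches the
    truth.  Bins partition [0, 1] into ``n_bins`` equal-width intervals, the
    first closed at its left edge and the rest left-open.  ECE is the
    bin-count-weighted mean absolute gap |acc(B_m) - conf(B_m)|; empty bins
    contribute 0.

    Returns the scalar ECE and the per-bin calibration table with columns
    ``bin_lo``, ``bin_hi``, ``count``, ``accuracy``, ``confidence``.
    """
    if n_bins < 1:
        raise InvalidParameterError(f"n_bins must be >= 1, got {n_bins}")
    mu_pred, truth = _check_aligned(mu_pred, truth)
    mu = mu_pred.astype(float)
    conf = np.maximum(mu, 1.0 - mu)
    correct = (mu >= 0.5).astype(int) == truth.astype(int)
    n = mu.shape[0]

    # (lo, hi] bins via ceil; confidence 0 falls in the closed first bin
    idx = np.ceil(conf * n_bins).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)

    counts = np.bincount(idx, minlength=n_bins)
    acc_sum = np.bincount(idx, weights=correct.astype(float), minlength=n_bins)
    conf_sum = np.bincount(idx, weights=conf, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        acc_bin = np.where(counts > 0, acc_sum / np.maximum(counts, 1), 0.0)
        conf_bin = np.where(counts > 0, conf_sum / np.maximum(counts, 1), 0.0)
    value = float(np.sum(counts / n * np.abs(acc_bin - conf_bin)))

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    table = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
            "accuracy": acc_bin,
            "confidence": conf_bin,
        }
    )
    return value, table


def brier(mu_pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared difference between predicted probability and outcome."""
    mu_pred, truth = _check_aligned(mu_pred, truth)
    return float(np.mean((mu_pred.astype(float) - truth.astype(float)) ** 2))


def auc_roc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Probability a random positive outranks a random negative (ties count 1/2)."""
    scores, truth = _check_aligned(scores, truth)
    if len(np.unique(truth)) < 2:
        raise UndefinedAUCError("AUC-ROC needs both classes present")
    return float(roc_auc_score(truth.astype(int), scores.astype(float)))


# ---------------------------------------------------------------------------
# percentage uncertainty
# ---------------------------------------------------------------------------


def percentage_uncertainty(traditional_pct: float, uq_pct: float) -> float:
    """Absolute gap, in percentage points, between a traditional metric and
    its uncertainty-aware counterpart (both already on the 0-100 scale),
    rounded to one decimal for reporting."""
    return round(abs(float(traditional_pct) - float(uq_pct)), 1)


# ---------------------------------------------------------------------------
# per-pass table I/O
# ---------------------------------------------------------------------------


def write_pass_table(samples: ProbabilitySample, labels: np.ndarray, path, sep: str = ",") -> None:
    """Write per-pass probabilities as a long table.

    Columns: ``instance_id``, ``pass``, ``prob``, ``label`` — one row per
    (forward pass, instance) pair, the standard exchange format between any
    external stochastic predictor and this module.
    """
    labels = np.asarray(labels).astype(int)
    if labels.shape[0] != samples.n_instances:
        raise InvalidInputError("labels length must match the number of instances")
    T, n = samples.n_passes, samples.n_instances
    frame = pd.DataFrame(
        {
            "instance_id": np.tile(np.arange(n), T),
            "pass": np.repeat(np.arange(T), n),
            "prob": samples.probs.ravel(),
            "label": np.tile(labels, T),
        }
    )
    frame.to_csv(path, index=False, sep=sep)


def read_pass_table(path, sep: str = ",") -> tuple[ProbabilitySample, np.ndarray]:
    """Read a long per-pass table back into a ProbabilitySample and labels."""
    frame = pd.read_csv(path, sep=sep)
    required = {"instance_id", "pass", "prob", "label"}
    if not required.issubset(frame.columns):
        raise InvalidInputError(f"pass table must have columns {sorted(required)}")
    wide = frame.pivot_table(index="pass", columns="instance_id", values="prob")
    labels = (
        frame.drop_duplicates("instance_id").sort_values("instance_id")["label"].to_numpy(int)
    )
    return ProbabilitySample(wide.to_numpy(float)), labels


# ---------------------------------------------------------------------------
# full evaluation of one task x technique
# ---------------------------------------------------------------------------


def evaluate_predictions(
    samples: ProbabilitySample,
    truth: np.ndarray,
    *,
    task: int | str,
    technique: str,
    threshold: float = 0.3,
    n_bins: int = 10,
) -> tuple[MetricReport, pd.DataFrame]:
    """Compute the full MetricReport for one one-vs-all task.

    Traditional metrics come from the thresholded predictive mean; the
    uncertainty-aware metrics from the correctness x certainty tally at the
    given normalized-entropy threshold; u_auc_roc is the AUC of the
    predictive mean against the true labels.  Returns the report and the
    per-bin calibration table.
    """
    truth = np.asarray(truth).astype(int)
    summary = summarize(samples, threshold)
    trad = traditional_metrics(binary_confusion(summary.predicted_label, truth))
    unc = u_metrics(uncertainty_confusion(summary.predicted_label, truth, summary.certain))
    ece_value, cal_table = ece(summary.mu_pred, truth, n_bins)
    deg = list(trad.degenerate) + list(unc.degenerate)
    try:
        auc = auc_roc(summary.mu_pred, truth)
    except UndefinedAUCError:
        auc = 0.0
        deg.append("auc_roc")
    report = MetricReport(
        task=task,
        technique=technique,
        threshold=float(threshold),
        accuracy=trad.accuracy,
        f1=trad.f1,
        precision=trad.precision,
        sensitivity=trad.sensitivity,
        specificity=trad.specificity,
        auc_roc=auc,
        u_acc=unc.u_acc,
        u_f1=unc.u_f1,
        u_prec=unc.u_prec,
        u_sens=unc.u_sens,
        u_spec=unc.u_spec,
        u_auc_roc=auc,
        ece=ece_value,
        brier=brier(summary.mu_pred, truth),
        degenerate=tuple(deg),
    )
    return report, cal_table
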