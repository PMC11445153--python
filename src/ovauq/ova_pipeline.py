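"""One-vs-All orchestration: rebalancing, binarization, train/sample/evaluate.

A C-class problem is decomposed into C binary tasks, one per class, each
discriminating that class (positive) from all the others (negative).  For
every task an independently trained stochastic predictor produces a
ProbabilitySample on the held-out split, from which the full traditional
and uncertainty-aware metric report is computed.

Class imbalance is removed beforehand by random oversampling: minority
classes are topped up with verbatim duplicates (drawn with replacement)
until every class matches the pre-balancing maximum.  Balancing is applied
to the whole dataset before the train/test split; duplicates of a row can
therefore land on both sides of the split, which slightly flatters
held-out metrics on duplicated rows (a caveat of dataset-level balancing,
not of the metrics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from . import samplers, uq_metrics
from .samplers import (
    BayesianMLP,
    DropoutMLP,
    ReferenceNetSpec,
    TrainConfig,
    ebnn_sample,
    emc_sample,
    ensemble_sample,
    mc_dropout_sample,
)
from .uq_metrics import InvalidInputError, InvalidParameterError, MetricReport

TECHNIQUES = ("mc_dropout", "ensemble", "emc", "bayes")


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix with integer class labels in {0..C-1}."""

    X: np.ndarray
    y: np.ndarray
    split: str | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
            raise InvalidInputError("X must be (n, d) aligned with 1-D labels")
        if y.size and y.min() < 0:
            raise InvalidInputError("labels must be non-negative")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1 if self.y.size else 0

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes)


@dataclass(frozen=True)
class OvATask:
    """One binary task: class ``positive_class`` against the rest."""

    positive_class: int
    X: np.ndarray
    y: np.ndarray  # 1 iff original label == positive_class
    degenerate: bool = False  # no positives present


@dataclass
class RunManifest:
    """Everything needed to reproduce an evaluation run exactly."""

    seed: int = 0
    techniques: tuple[str, ...] = TECHNIQUES
    threshold: float = 0.3
    n_passes: int = 50       # T: stochastic passes per task
    n_members: int = 5       # M: ensemble members
    test_fraction: float = 0.2
    epochs: int = 15
    batch_size: int = 64
    learning_rate: float = 1e-3
    n_bins: int = 10
    class_counts: tuple[int, ...] | None = None
    n_features: int = 150
    separation: float = 6.0
    sigma: float = 1.0
    dataset_path: str | None = None
    output_dir: str | None = None

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["techniques"] = list(self.techniques)
        if self.class_counts is not None:
            data["class_counts"] = list(self.class_counts)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunManifest":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown manifest keys: {sorted(unknown)}")
        if "techniques" in data:
            data = {**data, "techniques": tuple(data["techniques"])}
        if data.get("class_counts") is not None:
            data = {**data, "class_counts": tuple(data["class_counts"])}
        return cls(**data)


# ---------------------------------------------------------------------------
# rebalancing and binarization
# ---------------------------------------------------------------------------


def oversample_balance(dataset: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Random oversampling: duplicate minority rows until all classes match
    the majority count.  Added rows are verbatim copies drawn with
    replacement; already-balanced data is returned unchanged."""
    counts = dataset.class_counts()
    if np.any(counts == 0):
        raise InvalidInputError("every class in 0..C-1 must have at least one instance")
    target = int(counts.max())
    if np.all(counts == target):
        return dataset
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [dataset.X], [dataset.y]
    for k, count in enumerate(counts):
        deficit = target - int(count)
        if deficit > 0:
            pool = np.flatnonzero(dataset.y == k)
            picks = rng.choice(pool, size=deficit, replace=True)
            X_parts.append(dataset.X[picks])
            y_parts.append(np.full(deficit, k, dtype=int))
    return LabeledDataset(X=np.vstack(X_parts), y=np.concatenate(y_parts), split=dataset.split)


def binarize(dataset: LabeledDataset, positive_class: int) -> OvATask:
    """Binary labels for the class-k-vs-rest task."""
    if not (0 <= positive_class < max(dataset.n_classes, 1)):
        raise InvalidParameterError(
            f"positive_class {positive_class} out of range for {dataset.n_classes} classes"
        )
    y_bin = (dataset.y == positive_class).astype(int)
    return OvATask(
        positive_class=positive_class,
        X=dataset.X,
        y=y_bin,
        degenerate=bool(y_bin.sum() == 0),
    )


def make_tasks(dataset: LabeledDataset) -> list[OvATask]:
    return [binarize(dataset, k) for k in range(dataset.n_classes)]


# ---------------------------------------------------------------------------
# per-task training and evaluation
# ---------------------------------------------------------------------------


def _split_task(task: OvATask, test_fraction: float, seed: int):
    return train_test_split(
        task.X, task.y, test_size=test_fraction, stratify=task.y, random_state=seed
    )


def _seed_for(seed: int, *tags: int) -> int:
    """Stable derived seed below 2**31 for a (run seed, tag...) combination."""
    ss = np.random.SeedSequence([int(seed), *map(int, tags)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


_TECH_TAG = {"baseline": 0, "mc_dropout": 1, "ensemble": 2, "emc": 3, "bayes": 4}


def _train_members(kind, n_members, net_spec, cfg, X, y, seed, task_k, tech_tag):
    members = []
    for m in range(n_members):
        s = _seed_for(seed, task_k, tech_tag, m)
        model = kind(net_spec, seed=s)
        model.fit(X, y, TrainConfig(
            learning_rate=cfg.learning_rate, epochs=cfg.epochs,
            batch_size=cfg.batch_size, seed=s,
        ))
        members.append(model)
    return members


def run_task(
    task: OvATask,
    technique: str,
    manifest: RunManifest,
    net_spec: ReferenceNetSpec | None = None,
) -> tuple[MetricReport, pd.DataFrame]:
    """Train, sample and evaluate one task with one technique.

    ``technique`` is one of ``mc_dropout`` (one dropout net, T MC passes),
    ``ensemble`` (M nets, one deterministic pass each), ``emc`` (M dropout
    nets, T/M MC passes each), ``bayes`` (an ensemble of M mean-field
    Gaussian-weight nets, T/M posterior draws each) or ``baseline`` (one
    net, dropout off, a single deterministic pass).  Returns the metric
    report and the per-bin calibration table for the held-out split.
    """
    if technique not in (*TECHNIQUES, "baseline"):
        raise InvalidParameterError(f"unknown technique {technique!r}")
    if task.degenerate or len(np.unique(task.y)) < 2:
        raise InvalidInputError(
            f"task class {task.positive_class} is degenerate (single class present)"
        )
    if net_spec is None:
        net_spec = ReferenceNetSpec(input_dim=task.X.shape[1])
    cfg = manifest
    k = task.positive_class
    tag = _TECH_TAG[technique]
    X_tr, X_te, y_tr, y_te = _split_task(task, cfg.test_fraction, _seed_for(cfg.seed, k, 99))
    sample_seed = _seed_for(cfg.seed, k, tag, 1000)

    if technique in ("baseline", "mc_dropout"):
        model = _train_members(DropoutMLP, 1, net_spec, cfg, X_tr, y_tr, cfg.seed, k, tag)[0]
        if technique == "baseline":
            sample = ensemble_sample([model], X_te)
        else:
            sample = mc_dropout_sample(model, X_te, cfg.n_passes, sample_seed)
    elif technique == "ensemble":
        members = _train_members(DropoutMLP, cfg.n_members, net_spec, cfg, X_tr, y_tr, cfg.seed, k, tag)
        sample = ensemble_sample(members, X_te)
    elif technique == "emc":
        members = _train_members(DropoutMLP, cfg.n_members, net_spec, cfg, X_tr, y_tr, cfg.seed, k, tag)
        per = max(1, cfg.n_passes // cfg.n_members)
        sample = emc_sample(members, X_te, per, sample_seed)
    else:  # bayes: ensemble of Bayesian networks
        bspec = ReferenceNetSpec(
            input_dim=net_spec.input_dim, hidden=net_spec.hidden, dropout_rate=0.0
        )
        members = _train_members(BayesianMLP, cfg.n_members, bspec, cfg, X_tr, y_tr, cfg.seed, k, tag)
        per = max(1, cfg.n_passes // cfg.n_members)
        sample = ebnn_sample(members, X_te, per, sample_seed)

    return uq_metrics.evaluate_predictions(
        sample, y_te, task=k, technique=technique,
        threshold=cfg.threshold, n_bins=cfg.n_bins,
    )


def run_experiment(
    dataset: LabeledDataset, manifest: RunManifest
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Balance, binarize and evaluate every task with the baseline and every
    configured technique.

    Returns ``(metrics, calibration, deltas)``: one metrics row per
    task x technique (baseline included), the per-bin calibration tables,
    and the percentage-uncertainty delta table against the baseline.
    """
    balanced = oversample_balance(dataset, seed=_seed_for(manifest.seed, 7))
    reports: list[MetricReport] = []
    cal_frames = []
    for task in make_tasks(balanced):
        for technique in ("baseline", *manifest.techniques):
            report, cal = run_task(task, technique, manifest)
            reports.append(report)
            cal = cal.copy()
            cal.insert(0, "technique", technique)
            cal.insert(0, "task", task.positive_class)
            cal_frames.append(cal)
    metrics = pd.DataFrame([r.as_dict() for r in reports])
    calibration = pd.concat(cal_frames, ignore_index=True)
    baseline = metrics[metrics.technique == "baseline"]
    deltas = aggregate(metrics[metrics.technique != "baseline"], baseline)
    return metrics, calibration, deltas


#: (uncertainty-aware column, traditional baseline column) pairs differenced
#: in the delta table
DELTA_PAIRS = (
    ("u_acc", "accuracy"),
    ("u_auc_roc", "auc_roc"),
    ("u_prec", "precision"),
    ("u_sens", "sensitivity"),
)


def aggregate(reports: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Percentage-uncertainty deltas of each technique against the baseline.

    Both inputs are metric tables with a ``task`` column and metric values
    as fractions; the result holds, per task x technique, the absolute gap
    in percentage points for UAcc, UAUC-ROC, UPrec and USens.
    """
    base_by_task = baseline.set_index("task")
    missing = set(reports["task"]) - set(base_by_task.index)
    if missing:
        raise InvalidInputError(f"no baseline rows for tasks {sorted(missing)}")
    rows = []
    for _, rep in reports.iterrows():
        base = base_by_task.loc[rep["task"]]
        row = {"task": rep["task"], "technique": rep["technique"]}
        for u_col, t_col in DELTA_PAIRS:
            row[f"{u_col}_delta"] = uq_metrics.percentage_uncertainty(
                100.0 * base[t_col], 100.0 * rep[u_col]
            )
        rows.append(row)
    return pd.DataFrame(rows)
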