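"""Synthetic fixtures: class-conditional feature data and calibrated probabilities.

The feature generator emulates the kind of flattened deep-feature vectors a
pretrained backbone produces for chest X-ray images of the three study
classes (Normal = 0, COVID-19 = 1, Pneumonia = 2): class-conditional
spherical Gaussians in d dimensions whose means sit at equal mutual
distance ``separation``, so the inter-class overlap — the aleatoric
difficulty — is a single controllable knob.  The default class counts
(732, 619, 526) mirror the study's pre-balancing distribution.

What it does *not* emulate: the covariance structure, heavy tails and
class-dependent anisotropy of real extracted features.  Passing tests on
these fixtures validates the machinery, not real-image performance.

The calibrated fixture draws mu ~ Uniform(0, 1) and y ~ Bernoulli(mu), so
the probabilities are perfectly calibrated by construction and the
empirical expected calibration error must shrink toward 0 as n grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ova_pipeline import LabeledDataset
from .uq_metrics import InvalidInputError


class InvalidSyntheticSpecError(ValueError):
    pass


#: pre-balancing class counts of the chest X-ray study:
#: 732 normal, 619 COVID-19, 526 pneumonia
DEFAULT_CLASS_COUNTS: tuple[int, ...] = (732, 619, 526)


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of a class-conditional Gaussian feature dataset."""

    class_counts: tuple[int, ...] = DEFAULT_CLASS_COUNTS
    n_features: int = 150
    separation: float = 6.0   # mutual distance between class means
    sigma: float = 1.0        # within-class spherical standard deviation
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_counts) < 2 or any(c < 1 for c in self.class_counts):
            raise InvalidSyntheticSpecError("need >= 2 classes with >= 1 instance each")
        if self.sigma <= 0:
            raise InvalidSyntheticSpecError("sigma must be > 0")
        if self.separation < 0:
            raise InvalidSyntheticSpecError("separation must be >= 0")
        if self.n_features < len(self.class_counts):
            raise InvalidSyntheticSpecError(
                "n_features must be >= number of classes to place simplex means"
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_counts)


@dataclass(frozen=True)
class CalibratedFixture:
    """Probabilities with labels drawn so that P(y=1 | mu) = mu exactly."""

    mu: np.ndarray
    labels: np.ndarray
    seed: int


def class_means(spec: SyntheticSpec) -> np.ndarray:
    """Means at mutual distance ``separation``: scaled coordinate-axis simplex.

    Placing mean k at (separation / sqrt(2)) * e_k gives every pair of means
    Euclidean distance exactly ``separation``.
    """
    means = np.zeros((spec.n_classes, spec.n_features))
    for k in range(spec.n_classes):
        means[k, k] = spec.separation / np.sqrt(2.0)
    return means


def make_features(spec: SyntheticSpec) -> LabeledDataset:
    """Draw class-conditional spherical Gaussian features with exact counts."""
    rng = np.random.default_rng(spec.seed)
    means = class_means(spec)
    blocks, labels = [], []
    for k, count in enumerate(spec.class_counts):
        blocks.append(means[k] + spec.sigma * rng.standard_normal((count, spec.n_features)))
        labels.append(np.full(count, k, dtype=int))
    return LabeledDataset(X=np.vstack(blocks), y=np.concatenate(labels))


def make_calibrated(n: int, seed: int = 0) -> CalibratedFixture:
    """Uniform probabilities with Bernoulli(mu) labels — calibrated by design."""
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    mu = rng.random(n)
    labels = (rng.random(n) < mu).astype(int)
    return CalibratedFixture(mu=mu, labels=labels, seed=seed)


def write_features_csv(dataset: LabeledDataset, path) -> None:
    """Write features as feat_0..feat_{d-1} columns plus a label column."""
    d = dataset.X.shape[1]
    frame = pd.DataFrame(dataset.X, columns=[f"feat_{i}" for i in range(d)])
    frame["label"] = dataset.y
    frame.to_csv(path, index=False)


def read_features_csv(path) -> LabeledDataset:
    frame = pd.read_csv(path)
    if "label" not in frame.columns:
        raise InvalidInputError("feature CSV must contain a 'label' column")
    y = frame.pop("label").to_numpy(dtype=int)
    return LabeledDataset(X=frame.to_numpy(dtype=float), y=y)
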