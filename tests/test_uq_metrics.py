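"""Metric mathematics against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ovauq
from ovauq.uq_metrics import (
    InvalidDistributionError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedAUCError,
)

# ---------------------------------------------------------------------------
# predictive mean and entropy
# ---------------------------------------------------------------------------


def test_predictive_mean_is_the_arithmetic_mean_over_passes():
    sample = ovauq.ProbabilitySample(np.array([[0.2], [0.4], [0.6]]))
    assert ovauq.predictive_mean(sample) == pytest.approx([0.4])

    constant = ovauq.ProbabilitySample(np.full((7, 3), 0.35))
    assert ovauq.predictive_mean(constant) == pytest.approx([0.35] * 3)


def test_predictive_mean_matches_loop_oracle():
    rng = np.random.default_rng(42)
    probs = rng.random((10, 50))
    got = ovauq.predictive_mean(ovauq.ProbabilitySample(probs))
    oracle = np.array([sum(probs[t, i] for t in range(10)) / 10 for i in range(50)])
    np.testing.assert_allclose(got, oracle, atol=1e-12, rtol=0)


def test_empty_or_out_of_range_samples_are_rejected():
    with pytest.raises(InvalidInputError):
        ovauq.ProbabilitySample(np.empty((0, 5)))
    with pytest.raises(InvalidInputError):
        ovauq.ProbabilitySample(np.array([[0.2, 1.3]]))


@pytest.mark.parametrize(
    "dist,expected",
    [
        ((0.5, 0.5), math.log(2)),
        ((1.0, 0.0), 0.0),
        ((0.9, 0.1), -(0.9 * math.log(0.9) + 0.1 * math.log(0.1))),
        ((0.25, 0.25, 0.25, 0.25), math.log(4)),
    ],
)
def test_predictive_entropy_closed_forms(dist, expected):
    assert ovauq.predictive_entropy(np.array(dist)) == pytest.approx(expected, abs=1e-12)


def test_predictive_entropy_rejects_invalid_distributions():
    with pytest.raises(InvalidDistributionError):
        ovauq.predictive_entropy(np.array([-0.1, 1.1]))
    with pytest.raises(InvalidDistributionError):
        ovauq.predictive_entropy(np.array([0.5, 0.6]))


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=6))
def test_entropy_bounded_by_log_class_count(raw):
    p = np.array(raw) / np.sum(raw)
    p = p / p.sum()  # renormalize exactly
    ent = ovauq.predictive_entropy(p)
    assert -1e-12 <= ent <= math.log(len(p)) + 1e-9


# ---------------------------------------------------------------------------
# certainty partitioning
# ---------------------------------------------------------------------------


def test_partition_certainty_boundary_and_limits():
    assert ovauq.partition_certainty(np.array([0.0]), 0.0).all()  # zero entropy: certain
    assert ovauq.partition_certainty(np.array([0.1, 0.999, 1.0]), 1.0).all()
    # boundary value counts as certain, strictly above is uncertain
    flags = ovauq.partition_certainty(np.array([0.3, 0.3000001]), 0.3)
    assert flags.tolist() == [True, False]


def test_partition_certainty_matches_elementwise_oracle():
    rng = np.random.default_rng(9)
    ents = rng.random(100)
    flags = ovauq.partition_certainty(ents, 0.30)
    oracle = [not (e > 0.30) for e in ents]
    assert flags.tolist() == oracle


def test_partition_certainty_rejects_bad_threshold():
    with pytest.raises(InvalidParameterError):
        ovauq.partition_certainty(np.array([0.5]), 1.5)


# ---------------------------------------------------------------------------
# confusion matrices and their metrics
# ---------------------------------------------------------------------------


def test_uncertainty_confusion_pure_cases():
    n = 10
    cm = ovauq.uncertainty_confusion(np.ones(n), np.ones(n), np.ones(n, bool))
    assert (cm.TC, cm.TU, cm.FC, cm.FU) == (10, 0, 0, 0)
    cm = ovauq.uncertainty_confusion(np.ones(7), np.zeros(7), np.zeros(7, bool))
    assert (cm.TC, cm.TU, cm.FC, cm.FU) == (0, 7, 0, 0)


def test_uncertainty_confusion_matches_tally_oracle():
    rng = np.random.default_rng(7)
    pred = rng.integers(0, 2, 200)
    truth = rng.integers(0, 2, 200)
    certain = rng.random(200) < 0.6
    cm = ovauq.uncertainty_confusion(pred, truth, certain)
    tally = {"TC": 0, "TU": 0, "FC": 0, "FU": 0}
    for p, t, c in zip(pred, truth, certain):
        if p == t and c:
            tally["TC"] += 1
        elif p != t and not c:
            tally["TU"] += 1
        elif p != t and c:
            tally["FC"] += 1
        else:
            tally["FU"] += 1
    assert (cm.TC, cm.TU, cm.FC, cm.FU) == (
        tally["TC"], tally["TU"], tally["FC"], tally["FU"]
    )
    assert cm.n == 200


def test_uncertainty_confusion_rejects_length_mismatch():
    with pytest.raises(InvalidInputError):
        ovauq.uncertainty_confusion(np.ones(3), np.ones(4), np.ones(3, bool))


@settings(deadline=None, derandomize=True)
@given(st.integers(1, 300), st.integers(0, 2**31 - 1))
def test_count_conservation(n, seed):
    rng = np.random.default_rng(seed)
    pred = rng.integers(0, 2, n)
    truth = rng.integers(0, 2, n)
    certain = rng.random(n) < 0.5
    ucm = ovauq.uncertainty_confusion(pred, truth, certain)
    bcm = ovauq.binary_confusion(pred, truth)
    assert ucm.TC + ucm.TU + ucm.FC + ucm.FU == n
    assert bcm.TP + bcm.TN + bcm.FP + bcm.FN == n


@pytest.mark.parametrize(
    "cells,expected",
    [
        ((25, 25, 25, 25), dict(u_acc=0.5, u_sens=0.5, u_spec=0.5, u_prec=0.5)),
        ((90, 5, 3, 2), dict(u_acc=0.95, u_sens=5 / 8, u_spec=90 / 92, u_prec=5 / 7)),
        ((10, 0, 0, 0), dict(u_acc=1.0, u_sens=0.0, u_spec=1.0, u_prec=0.0)),
    ],
)
def test_u_metrics_formulas(cells, expected):
    m = ovauq.u_metrics(ovauq.UncertaintyConfusionMatrix(*cells))
    for name, val in expected.items():
        assert getattr(m, name) == pytest.approx(val, abs=1e-12)


def test_u_metrics_flags_degenerate_ratios():
    m = ovauq.u_metrics(ovauq.UncertaintyConfusionMatrix(TC=10, TU=0, FC=0, FU=0))
    assert "u_sens" in m.degenerate and "u_prec" in m.degenerate
    with pytest.raises(InvalidInputError):
        ovauq.UncertaintyConfusionMatrix(TC=-1, TU=0, FC=0, FU=1)


@pytest.mark.parametrize(
    "cells,expected",
    [
        ((50, 50, 0, 0), dict(accuracy=1, sensitivity=1, specificity=1, precision=1, f1=1)),
        ((0, 0, 50, 50), dict(accuracy=0.0)),
        ((40, 45, 5, 10), dict(accuracy=0.85, sensitivity=0.8, specificity=0.9, precision=8 / 9)),
    ],
)
def test_traditional_metrics_formulas(cells, expected):
    m = ovauq.traditional_metrics(ovauq.BinaryConfusionMatrix(*cells))
    for name, val in expected.items():
        assert getattr(m, name) == pytest.approx(val, abs=1e-12)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def _ece_oracle(mu, truth, n_bins):
    """Loop-based binning: (lo, hi] bins, first bin closed at 0."""
    n = len(mu)
    conf = [max(m, 1 - m) for m in mu]
    correct = [(1 if m >= 0.5 else 0) == t for m, t in zip(mu, truth)]
    total = 0.0
    for b in range(n_bins):
        lo, hi = b / n_bins, (b + 1) / n_bins
        members = [
            i for i in range(n)
            if (conf[i] > lo or (b == 0 and conf[i] >= 0)) and conf[i] <= hi
        ]
        if not members:
            continue
        acc = sum(correct[i] for i in members) / len(members)
        avg_conf = sum(conf[i] for i in members) / len(members)
        total += len(members) / n * abs(acc - avg_conf)
    return total


def test_ece_perfectly_confident_extremes():
    mu = np.ones(20)
    value, _ = ovauq.ece(mu, np.ones(20, int), 10)
    assert value == pytest.approx(0.0, abs=1e-12)
    value, _ = ovauq.ece(mu, np.zeros(20, int), 10)
    assert value == pytest.approx(1.0, abs=1e-12)


def test_ece_matches_loop_oracle_and_table_is_consistent():
    rng = np.random.default_rng(31)
    mu = rng.random(500)
    truth = rng.integers(0, 2, 500)
    value, table = ovauq.ece(mu, truth, 10)
    assert value == pytest.approx(_ece_oracle(mu, truth, 10), abs=1e-12)
    assert table["count"].sum() == 500
    occupied = table[table["count"] > 0]
    assert ((occupied["accuracy"] >= 0) & (occupied["accuracy"] <= 1)).all()
    assert ((occupied["confidence"] >= 0) & (occupied["confidence"] <= 1)).all()


def test_ece_rejects_bad_bin_count():
    with pytest.raises(InvalidParameterError):
        ovauq.ece(np.array([0.5]), np.array([1]), 0)


def test_brier_closed_forms_and_oracle():
    y = np.array([0, 1, 1, 0])
    assert ovauq.brier(y.astype(float), y) == pytest.approx(0.0, abs=1e-15)
    assert ovauq.brier(np.full(4, 0.5), y) == pytest.approx(0.25, abs=1e-15)
    rng = np.random.default_rng(17)
    mu = rng.random(100)
    truth = rng.integers(0, 2, 100)
    oracle = sum((m - t) ** 2 for m, t in zip(mu, truth)) / 100
    assert ovauq.brier(mu, truth) == pytest.approx(oracle, abs=1e-12)


# ---------------------------------------------------------------------------
# AUC-ROC
# ---------------------------------------------------------------------------


def _auc_pair_oracle(scores, truth):
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def test_auc_trivial_cases():
    truth = np.array([0, 0, 1, 1])
    assert ovauq.auc_roc(np.array([0.1, 0.2, 0.8, 0.9]), truth) == pytest.approx(1.0)
    assert ovauq.auc_roc(np.full(4, 0.5), truth) == pytest.approx(0.5)
    with pytest.raises(UndefinedAUCError):
        ovauq.auc_roc(np.array([0.1, 0.9]), np.array([1, 1]))


def test_auc_matches_pair_counting_oracle():
    rng = np.random.default_rng(23)
    scores = np.round(rng.random(30), 1)  # coarse grid forces ties
    truth = rng.integers(0, 2, 30)
    if truth.sum() in (0, 30):
        truth[0] = 1 - truth[0]
    assert ovauq.auc_roc(scores, truth) == pytest.approx(
        _auc_pair_oracle(scores, truth), abs=1e-12
    )


# ---------------------------------------------------------------------------
# percentage uncertainty
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "trad,uq,expected",
    [
        (92.8, 81.0, 11.8),  # accuracy vs MC-dropout UAcc, first task
        (90.4, 93.3, 2.9),   # sensitivity vs Bayesian-ensemble USens
        (77.7, 77.7, 0.0),
        (89.7, 90.7, 1.0),   # sign-free: uncertainty-aware may exceed traditional
    ],
)
def test_percentage_uncertainty_absolute_difference(trad, uq, expected):
    assert ovauq.percentage_uncertainty(trad, uq) == expected


# ---------------------------------------------------------------------------
# summary and report assembly
# ---------------------------------------------------------------------------


def test_summarize_labels_and_certainty():
    probs = np.array([[0.9, 0.5, 0.1], [0.8, 0.5, 0.2]])
    summary = ovauq.summarize(ovauq.ProbabilitySample(probs), threshold=0.9)
    np.testing.assert_array_equal(summary.predicted_label, [1, 1, 0])  # tie -> positive
    assert summary.mu_pred == pytest.approx([0.85, 0.5, 0.15])
    # mu = 0.5 has maximal normalized entropy 1 > 0.9 threshold
    assert summary.certain.tolist() == [True, False, True]
    assert np.all((summary.entropy_norm >= 0) & (summary.entropy_norm <= 1))


def test_threshold_limits_tie_u_acc_to_accuracy():
    rng = np.random.default_rng(3)
    probs = 0.2 + 0.6 * rng.random((15, 80))  # interior probabilities: entropy > 0
    truth = rng.integers(0, 2, 80)
    sample = ovauq.ProbabilitySample(probs)
    report_all_certain, _ = ovauq.evaluate_predictions(
        sample, truth, task=0, technique="x", threshold=1.0
    )
    assert report_all_certain.u_acc == report_all_certain.accuracy
    min_ent = ovauq.summarize(sample, 0.5).entropy_norm.min()
    assert min_ent > 0
    report_all_uncertain, _ = ovauq.evaluate_predictions(
        sample, truth, task=0, technique="x", threshold=min_ent / 2
    )
    assert report_all_uncertain.u_acc == pytest.approx(
        1.0 - report_all_uncertain.accuracy, abs=1e-15
    )


def test_pass_table_roundtrip(tmp_path):
    rng = np.random.default_rng(8)
    sample = ovauq.ProbabilitySample(rng.random((6, 9)))
    labels = rng.integers(0, 2, 9)
    path = tmp_path / "passes.csv"
    ovauq.uq_metrics.write_pass_table(sample, labels, path)
    back, labels_back = ovauq.uq_metrics.read_pass_table(path)
    np.testing.assert_allclose(back.probs, sample.probs, atol=1e-12)
    np.testing.assert_array_equal(labels_back, labels)
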