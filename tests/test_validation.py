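"""Validation machinery vs independent oracles.

AUC is checked against a brute-force concordance-pair count and against
scikit-learn; DeLong confidence intervals against values computed with R's
pROC (``ci.auc(..., method="delong")``) on a fixed dataset, frozen below;
optimal-cutpoint selection against an exhaustive scan.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from icddx import (
    ConfusionCounts,
    DegenerateLabelsError,
    MissingCategoryError,
    MissingLabelError,
    confusion_at_cutoff,
    cutoff_table,
    false_positive_audit,
    metrics,
    optimal_cutoffs,
    roc_auc,
)
from icddx.validation import CutoffRow
from .conftest import make_record, make_records


def brute_force_auc(pos, neg) -> float:
    """Concordance probability by exhaustive cross-class pair counting."""
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# confusion counts and metrics


def study_records():
    """Records reproducing the study's cutoff >= 2 contingency structure:
    101 discrepant at >= 5 steps, 162 non-discrepant at 2+ steps
    (88 precision, 60 complication, 14 identical), 933 below 2 steps."""
    recs = []
    recs += [make_record(f"D{i}", 6, True, "diagnostically_different") for i in range(101)]
    recs += [make_record(f"FP{i}", 2, False, "precision") for i in range(88)]
    recs += [make_record(f"FC{i}", 4, False, "complication") for i in range(60)]
    recs += [make_record(f"FI{i}", 2, False, "identical") for i in range(14)]
    recs += [make_record(f"N{i}", 0, False, "identical") for i in range(933)]
    return recs


def test_confusion_reproduces_study_counts():
    c = confusion_at_cutoff(study_records(), "steps", 2.0)
    assert c == ConfusionCounts(tp=101, fp=162, fn=0, tn=933)


def test_confusion_above_diameter_flags_nothing():
    c = confusion_at_cutoff(study_records(), "steps", 11.0)
    assert c == ConfusionCounts(tp=0, fp=0, fn=101, tn=1095)


def test_confusion_empty_input_is_all_zero():
    assert confusion_at_cutoff([], "steps", 2.0) == ConfusionCounts(0, 0, 0, 0)


def test_confusion_requires_labels():
    with pytest.raises(MissingLabelError):
        confusion_at_cutoff([make_record("P1", 2, None)], "steps", 2.0)


def test_metrics_from_study_counts():
    m = metrics(ConfusionCounts(tp=101, fp=162, fn=0, tn=933))
    assert m.sensitivity == 1.0
    assert m.fpr == pytest.approx(162 / 1095)  # ~0.148, printed as 15%
    assert m.ppv == pytest.approx(101 / 263)  # 0.384: 263 flagged for review
    assert m.npv == 1.0
    assert m.fnr == 0.0


def test_metrics_all_flagged_row():
    m = metrics(ConfusionCounts(tp=101, fp=1103, fn=0, tn=0))
    assert m.ppv == pytest.approx(101 / 1204)  # prevalence, 8.4%
    assert m.specificity == 0.0
    assert m.npv is None  # printed as "-"


def test_metrics_degenerate_counts_are_missing():
    m = metrics(ConfusionCounts(0, 0, 0, 0))
    assert (
        m.sensitivity is m.specificity is m.fpr is m.fnr is m.ppv is m.npv
        is m.youden_j is None
    )


def test_metric_identities_hold_wherever_defined():
    rng = np.random.default_rng(5)
    for _ in range(50):
        tp, fp, fn, tn = (int(v) for v in rng.integers(0, 20, size=4))
        m = metrics(ConfusionCounts(tp, fp, fn, tn))
        if m.specificity is not None:
            assert m.fpr + m.specificity == pytest.approx(1.0)
        if m.sensitivity is not None:
            assert m.fnr + m.sensitivity == pytest.approx(1.0)
        if m.youden_j is not None:
            assert m.youden_j == pytest.approx(m.sensitivity + m.specificity - 1)


# ---------------------------------------------------------------------------
# cutoff table


def test_cutoff_table_sorted_and_monotone():
    table = cutoff_table(study_records(), "steps")
    cuts = [row.cutoff for row in table]
    assert cuts == sorted(cuts, reverse=True)
    sens = [row.sensitivity for row in table]
    spec = [row.specificity for row in table]
    assert sens == sorted(sens)  # nondecreasing as the cutoff decreases
    assert spec == sorted(spec, reverse=True)


def test_cutoff_table_single_cutoff_zero_flags_all():
    (row,) = cutoff_table(study_records(), "steps", [0.0])
    assert row.specificity == 0.0
    assert row.sensitivity == 1.0
    assert row.counts.tn == 0


def test_cutoff_table_inverse_construction():
    """Cohort built to hit (sens, spec) = (1.00, 0.85) at cutoff 2 and
    (0.90, 0.90) at cutoff 5; verified by brute-force recount."""
    scores = [5] * 18 + [2] * 2 + [0] * 34 + [2] * 2 + [5] * 4
    labels = [True] * 20 + [False] * 40
    recs = make_records(scores, labels)
    rows = {r.cutoff: r for r in cutoff_table(recs, "steps", [2, 5])}
    assert rows[2.0].sensitivity == pytest.approx(1.00)
    assert rows[2.0].specificity == pytest.approx(0.85)
    assert rows[5.0].sensitivity == pytest.approx(0.90)
    assert rows[5.0].specificity == pytest.approx(0.90)
    # brute-force recount oracle
    for cut, row in rows.items():
        tp = sum(1 for s, l in zip(scores, labels) if l and s >= cut)
        fp = sum(1 for s, l in zip(scores, labels) if not l and s >= cut)
        assert (row.counts.tp, row.counts.fp) == (tp, fp)
        assert row.counts.total == 60


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


def test_auc_perfect_separation():
    recs = make_records([5, 6, 7, 0, 1, 2], [1, 1, 1, 0, 0, 0])
    assert roc_auc(recs, "steps").auc == 1.0


def test_auc_uninformative_scores_near_half():
    rng = np.random.default_rng(42)
    scores = rng.integers(0, 10, size=4000)
    labels = rng.random(4000) < 0.3
    recs = make_records(scores, labels)
    assert roc_auc(recs, "steps").auc == pytest.approx(0.5, abs=0.03)


def test_auc_six_record_worked_example():
    # positives 2,3,4 vs negatives 1,2,3: 9 cross pairs, brute-force count
    recs = make_records([2, 3, 4, 1, 2, 3], [1, 1, 1, 0, 0, 0])
    expected = brute_force_auc([2, 3, 4], [1, 2, 3])
    assert expected == 7 / 9
    assert roc_auc(recs, "steps").auc == pytest.approx(expected)


def test_auc_equals_brute_force_on_random_small_cohorts():
    rng = np.random.default_rng(1234)
    for trial in range(25):
        n = int(rng.integers(4, 51))
        scores = rng.integers(0, 8, size=n)
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            continue
        recs = make_records(scores, labels)
        expected = brute_force_auc(scores[labels], scores[~labels])
        res = roc_auc(recs, "steps")
        assert res.auc == pytest.approx(expected, abs=1e-12)
        assert res.auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )  # independent library cross-check
        assert res.auc_ci_low <= res.auc <= res.auc_ci_high


def test_delong_ci_matches_pROC():
    """Frozen oracle: R pROC 1.19, ci.auc(..., method='delong') on this data."""
    neg = [0, 0, 0, 1, 1, 2, 2, 4, 6, 0, 1, 2]
    pos = [2, 5, 6, 8, 8, 10]
    recs = make_records(pos + neg, [True] * len(pos) + [False] * len(neg))
    res = roc_auc(recs, "steps")
    assert res.auc == pytest.approx(0.930555555555556, abs=1e-12)
    assert res.auc_se == pytest.approx(0.058357378401681, abs=1e-12)
    assert res.auc_ci_low == pytest.approx(0.816177195656086, abs=1e-9)
    assert res.auc_ci_high == 1.0  # clipped to [0, 1]


def test_auc_invariant_under_monotone_transforms():
    rng = np.random.default_rng(99)
    steps = rng.integers(0, 9, size=80)
    labels = np.concatenate([np.ones(30, bool), rng.random(50) < 0.2])
    transforms = [lambda v: 3.0 * v + 1.0, lambda v: v**3, lambda v: math.expm1(v)]
    base = roc_auc(make_records(steps, labels), "steps").auc
    for f in transforms:
        recs = [
            make_record(f"P{i}", s, bool(l), weighted=f(float(s)))
            for i, (s, l) in enumerate(zip(steps, labels))
        ]
        assert roc_auc(recs, "weighted").auc == pytest.approx(base, abs=1e-12)
    # similarity polarity: a decreasing transform scored as a similarity
    recs = [
        make_record(f"P{i}", s, bool(l), li=math.exp(-float(s)))
        for i, (s, l) in enumerate(zip(steps, labels))
    ]
    assert roc_auc(recs, "li").auc == pytest.approx(base, abs=1e-12)


def test_roc_points_trapezoid_equals_concordance_auc():
    rng = np.random.default_rng(3)
    scores = rng.integers(0, 6, size=60)  # heavy ties -> diagonal segments
    labels = rng.random(60) < 0.35
    recs = make_records(scores, labels)
    res = roc_auc(recs, "steps")
    pts = res.operating_points
    assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
    trapezoid = sum(
        (x2 - x1) * (y1 + y2) / 2.0
        for (x1, y1), (x2, y2) in zip(pts, pts[1:])
    )
    assert trapezoid == pytest.approx(res.auc, abs=1e-12)


def test_single_class_raises():
    with pytest.raises(DegenerateLabelsError):
        roc_auc(make_records([1, 2, 3], [1, 1, 1]), "steps")


# ---------------------------------------------------------------------------
# optimal cutpoints


def random_table(rng) -> list[CutoffRow]:
    rows = []
    for cutoff in range(int(rng.integers(2, 12))):
        tp, fp, fn, tn = (int(v) for v in rng.integers(0, 30, size=4))
        rows.append(metrics(ConfusionCounts(tp, fp, fn, tn), cutoff=float(cutoff)))
    return rows


def oracle_optimal(table, primary, secondary):
    """Exhaustive scan with explicit comparisons, independent of the
    implementation's sort-key formulation."""
    best = None
    for row in table:
        p = getattr(row, primary)
        if p is None:
            continue
        s = getattr(row, secondary)
        s = -1.0 if s is None else s
        key = (p, s, row.cutoff)
        if best is None or key > best[0]:
            best = (key, row.cutoff)
    return None if best is None else best[1]


def test_optimal_cutoffs_match_exhaustive_scan_on_random_tables():
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 100:
        table = random_table(rng)
        if all(r.sensitivity is None for r in table) or all(
            r.specificity is None for r in table
        ):
            continue
        got = optimal_cutoffs(table)
        assert got["max_sensitivity"] == oracle_optimal(table, "sensitivity", "specificity")
        assert got["max_specificity"] == oracle_optimal(table, "specificity", "sensitivity")
        if any(r.youden_j is not None for r in table):
            assert got["youden"] == oracle_optimal(table, "youden_j", "specificity")
        checked += 1


def test_max_sensitivity_tiebreak_prefers_larger_cutoff():
    # sensitivity 1.00 at cutoffs 0-2, specificity 0.00/0.85/0.85: pick 2
    table = [
        metrics(ConfusionCounts(10, 100, 0, 0), cutoff=0.0),
        metrics(ConfusionCounts(10, 15, 0, 85), cutoff=1.0),
        metrics(ConfusionCounts(10, 15, 0, 85), cutoff=2.0),
    ]
    assert optimal_cutoffs(table)["max_sensitivity"] == 2.0


def test_optimal_cutoffs_single_row():
    table = [metrics(ConfusionCounts(5, 2, 1, 10), cutoff=3.0)]
    assert optimal_cutoffs(table) == {
        "max_sensitivity": 3.0,
        "max_specificity": 3.0,
        "youden": 3.0,
    }


# ---------------------------------------------------------------------------
# false-positive audit


def test_audit_reproduces_study_decomposition():
    audit = false_positive_audit(study_records(), "steps", 2.0)
    assert audit.n_false_positive == 162
    assert audit.by_category["precision"] == (88, pytest.approx(88 / 162))  # 54%
    assert audit.by_category["complication"] == (60, pytest.approx(60 / 162))  # 37%
    assert audit.by_category["identical"] == (14, pytest.approx(14 / 162))  # 9%
    assert audit.true_npv == pytest.approx(148 / 162)  # 91%
    assert sum(cnt for cnt, _ in audit.by_category.values()) == audit.n_false_positive


def test_audit_zero_false_positives():
    recs = make_records([5, 0], [True, False], ["diagnostically_different", "identical"])
    audit = false_positive_audit(recs, "steps", 2.0)
    assert audit.n_false_positive == 0
    assert audit.by_category == {}
    assert audit.true_npv is None


def test_audit_requires_categories_on_false_positives():
    recs = [make_record("P1", 4, False, None)]
    with pytest.raises(MissingCategoryError):
        false_positive_audit(recs, "steps", 2.0)


def test_audit_partition_invariant_random():
    rng = np.random.default_rng(8)
    cats = ["identical", "precision", "complication"]
    recs = [
        make_record(f"P{i}", int(rng.integers(0, 8)), False, cats[int(rng.integers(0, 3))])
        for i in range(120)
    ] + [make_record("T0", 9, True, "diagnostically_different")]
    for cutoff in (1.0, 3.0, 6.0):
        audit = false_positive_audit(recs, "steps", cutoff)
        assert sum(c for c, _ in audit.by_category.values()) == audit.n_false_positive
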