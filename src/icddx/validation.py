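"""Validation of the trigger against expert reference labels.

Given screening records that carry both a score and an expert label
(discrepant yes/no), this module computes

* confusion counts and screening metrics (sensitivity, specificity, FPR,
  FNR, PPV, NPV, Youden's J) across a grid of cutoffs — the cutoff-sweep
  table a study would print;
* the ROC curve and its area, where the AUC is the tie-corrected
  concordance probability ``P(score_case > score_control) + 0.5 P(equal)``
  with polarity mapped so that larger always means more discrepant, and a
  95% confidence interval from DeLong's asymptotic variance of the
  Mann-Whitney statistic (midrank structural components);
* optimal cutpoints (maximum sensitivity, maximum specificity, maximum
  Youden's J) with explicit tie-breaking;
* the false-positive decomposition: which expert rating categories the
  flagged-but-non-discrepant cases fall into, and the "true NPV" — the
  share of false positives that are at least not identical diagnoses.

Records without a score (no documented follow-up, or skipped unknown codes)
must be filtered out by the caller before these functions; use
:func:`scored_labeled`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DegenerateLabelsError, MissingCategoryError, MissingLabelError
from .screening import ScreeningRecord, crosses_cutoff
from .similarity import is_distance


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class CutoffRow:
    """One row of the cutoff-sweep table; metrics are None when undefined."""

    cutoff: float
    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    fpr: float | None
    fnr: float | None
    ppv: float | None
    npv: float | None
    youden_j: float | None


@dataclass(frozen=True)
class ROCResult:
    operating_points: tuple[tuple[float, float], ...]
    auc: float
    auc_se: float
    auc_ci_low: float
    auc_ci_high: float


@dataclass(frozen=True)
class FalsePositiveAudit:
    n_false_positive: int
    by_category: dict[str, tuple[int, float]]  # category -> (count, proportion)
    true_npv: float | None


def scored_labeled(records: Iterable[ScreeningRecord]) -> list[ScreeningRecord]:
    """Records eligible for validation: scored and expert-labeled."""
    return [
        r
        for r in records
        if r.score is not None and r.reference_label is not None
    ]


def _score_value(record: ScreeningRecord, algorithm: str) -> float:
    if record.score is None:
        raise MissingLabelError(
            f"record {record.patient_id!r} has no score; filter unscored "
            "records (scored_labeled) before validation"
        )
    return record.score.value(algorithm)


def _label(record: ScreeningRecord) -> bool:
    if record.reference_label is None:
        raise MissingLabelError(
            f"record {record.patient_id!r} has no reference label"
        )
    return record.reference_label


def confusion_at_cutoff(
    records: Sequence[ScreeningRecord], algorithm: str, cutoff: float
) -> ConfusionCounts:
    """Cross-classify expert label vs flag at one cutoff."""
    tp = fp = fn = tn = 0
    for r in records:
        label = _label(r)
        flagged = crosses_cutoff(_score_value(r, algorithm), algorithm, cutoff)
        if label and flagged:
            tp += 1
        elif label:
            fn += 1
        elif flagged:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def metrics(c: ConfusionCounts, cutoff: float = float("nan")) -> CutoffRow:
    """Derive screening metrics from confusion counts (None if denominator 0)."""
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    return CutoffRow(
        cutoff=cutoff,
        counts=c,
        sensitivity=sens,
        specificity=spec,
        fpr=None if spec is None else 1.0 - spec,
        fnr=None if sens is None else 1.0 - sens,
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        youden_j=None if sens is None or spec is None else sens + spec - 1.0,
    )


def default_grid(
    records: Sequence[ScreeningRecord], algorithm: str
) -> list[float]:
    """Distinct observed scores, plus 0 and max+1 for distance algorithms."""
    values = {_score_value(r, algorithm) for r in records}
    if is_distance(algorithm):
        values |= {0.0, (max(values) if values else 0.0) + 1.0}
    return sorted(values)


def cutoff_table(
    records: Sequence[ScreeningRecord],
    algorithm: str,
    cutoffs: Sequence[float] | None = None,
) -> list[CutoffRow]:
    """One metrics row per cutoff, sorted descending by cutoff."""
    grid = list(cutoffs) if cutoffs is not None else default_grid(records, algorithm)
    if not grid:
        raise ValueError("cutoff grid is empty")
    return [
        metrics(confusion_at_cutoff(records, algorithm, c), cutoff=float(c))
        for c in sorted(grid, reverse=True)
    ]


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


def _discrepancy_scores(
    records: Sequence[ScreeningRecord], algorithm: str
) -> tuple[np.ndarray, np.ndarray]:
    """Scores on a larger-is-more-discrepant scale, split by label."""
    sign = 1.0 if is_distance(algorithm) else -1.0
    pos = [sign * _score_value(r, algorithm) for r in records if _label(r)]
    neg = [sign * _score_value(r, algorithm) for r in records if not _label(r)]
    if not pos or not neg:
        raise DegenerateLabelsError(
            "ROC analysis needs both discrepant and non-discrepant records; "
            f"got {len(pos)} positive and {len(neg)} negative"
        )
    return np.asarray(pos, dtype=float), np.asarray(neg, dtype=float)


def _delong_auc(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong standard error via midrank structural components."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = rankdata(all_scores)  # midranks
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # structural components: v10[i] = mean_j psi(X_i, Y_j), v01 analogous
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    return float(auc), se


def _operating_points(
    pos: np.ndarray, neg: np.ndarray
) -> tuple[tuple[float, float], ...]:
    """(FPR, TPR) per distinct threshold, augmented with (0,0) and (1,1)."""
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    m, n = len(pos), len(neg)
    points = [(0.0, 0.0)]
    for thr in thresholds:
        tpr = float((pos >= thr).sum()) / m
        fpr = float((neg >= thr).sum()) / n
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    # deduplicate while preserving order
    out: list[tuple[float, float]] = []
    for pt in points:
        if not out or pt != out[-1]:
            out.append(pt)
    return tuple(out)


def roc_auc(
    records: Sequence[ScreeningRecord],
    algorithm: str,
    confidence: float = 0.95,
) -> ROCResult:
    """ROC curve, concordance AUC and DeLong confidence interval."""
    pos, neg = _discrepancy_scores(records, algorithm)
    auc, se = _delong_auc(pos, neg)
    z = float(norm.ppf(0.5 + confidence / 2.0))
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return ROCResult(
        operating_points=_operating_points(pos, neg),
        auc=auc,
        auc_se=se,
        auc_ci_low=lo,
        auc_ci_high=hi,
    )


# ---------------------------------------------------------------------------
# optimal cutpoints


def optimal_cutoffs(table: Sequence[CutoffRow]) -> dict[str, float]:
    """Optimal cutoffs by three criteria with deterministic tie-breaking.

    * ``max_sensitivity``: highest sensitivity; ties by higher specificity,
      then by larger cutoff (flag as little as possible).
    * ``max_specificity``: highest specificity; ties by higher sensitivity,
      then larger cutoff.
    * ``youden``: maximum J = sensitivity + specificity - 1; ties by higher
      specificity, then larger cutoff.
    """
    if not table:
        raise ValueError("cutoff table is empty")

    def pick(primary: str, secondary: str) -> float:
        rows = [r for r in table if getattr(r, primary) is not None]
        if not rows:
            raise ValueError(f"no row defines {primary}")
        best = max(
            rows,
            key=lambda r: (
                getattr(r, primary),
                getattr(r, secondary) if getattr(r, secondary) is not None else -1.0,
                r.cutoff,
            ),
        )
        return best.cutoff

    return {
        "max_sensitivity": pick("sensitivity", "specificity"),
        "max_specificity": pick("specificity", "sensitivity"),
        "youden": pick("youden_j", "specificity"),
    }


# ---------------------------------------------------------------------------
# false-positive audit


def false_positive_audit(
    records: Sequence[ScreeningRecord],
    algorithm: str = "steps",
    cutoff: float = 2.0,
) -> FalsePositiveAudit:
    """Decompose flagged-but-non-discrepant records by expert rating category.

    ``true_npv`` is the share of false positives whose rating is anything
    but ``identical`` — cases where the flag, while formally wrong against
    the discrepancy label, still points at a genuinely changed diagnosis
    (refined precision or a new complication).
    """
    by_cat: dict[str, int] = {}
    n_fp = 0
    for r in records:
        if _label(r):
            continue
        if not crosses_cutoff(_score_value(r, algorithm), algorithm, cutoff):
            continue
        n_fp += 1
        if r.rating_category is None:
            raise MissingCategoryError(
                f"false-positive record {r.patient_id!r} lacks a rating category"
            )
        by_cat[r.rating_category] = by_cat.get(r.rating_category, 0) + 1
    if n_fp == 0:
        return FalsePositiveAudit(0, {}, None)
    return FalsePositiveAudit(
        n_false_positive=n_fp,
        by_category={
            cat: (cnt, cnt / n_fp) for cat, cnt in sorted(by_cat.items())
        },
        true_npv=1.0 - by_cat.get("identical", 0) / n_fp,
    )
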