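"""The trigger tool: score paired diagnoses and flag potential discrepancies.

Each patient contributes an index (ED discharge) diagnosis and zero or more
follow-up diagnoses established within the follow-up window. The screen
scores the pair with one of the four tree algorithms and flags it when the
value crosses a cutoff — ``value >= cutoff`` for distances, ``value <=
cutoff`` for similarities (e.g. flag at ">= 2 hierarchical steps").

Rules taken from the study design:

* A patient with no documented follow-up care is assumed to have no change
  in diagnosis: never flagged, never scored.
* When the follow-up letter lists several diagnoses, the effective follow-up
  is the one *closest* to the index diagnosis (minimum distance / maximum
  similarity): a letter that still contains the ED diagnosis is not a
  relabeling.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import FormatError, UnknownCodeError
from .similarity import (
    ALGORITHMS,
    EdgeWeightScheme,
    LiParameters,
    PairScore,
    is_distance,
    score_pair,
)
from .taxonomy import ROOT_CODE, Taxonomy, normalize_code

RATING_CATEGORIES = (
    "identical",
    "precision",
    "complication",
    "diagnostically_different",
    "hierarchically_different",
)
#: Rating categories that constitute an expert-confirmed discrepancy.
DISCREPANT_CATEGORIES = frozenset(
    {"diagnostically_different", "hierarchically_different"}
)

PAIRS_COLUMNS = (
    "patient_id",
    "index_code",
    "followup_codes",
    "reference_label",
    "rating_category",
)

RECORD_COLUMNS = (
    "patient_id",
    "index_code",
    "effective_followup",
    "steps",
    "weighted",
    "wu_palmer",
    "li",
    "lca_depth",
    "lca_code",
    "flagged",
    "flag_reason",
    "reference_label",
    "rating_category",
)


@dataclass(frozen=True)
class DiagnosisPair:
    """One patient's index diagnosis, follow-up diagnoses and expert rating."""

    patient_id: str
    index_code: str
    followup_codes: tuple[str, ...] = ()
    reference_label: bool | None = None
    rating_category: str | None = None

    def __post_init__(self) -> None:
        if self.rating_category is not None:
            if self.rating_category not in RATING_CATEGORIES:
                raise FormatError(
                    f"unknown rating category {self.rating_category!r} "
                    f"for patient {self.patient_id!r}"
                )
            if self.reference_label is not None:
                implied = self.rating_category in DISCREPANT_CATEGORIES
                if self.reference_label != implied:
                    raise FormatError(
                        f"patient {self.patient_id!r}: reference_label "
                        f"{self.reference_label} contradicts rating category "
                        f"{self.rating_category!r}"
                    )


@dataclass(frozen=True)
class ScreeningRecord:
    """Outcome of screening one pair at a given algorithm and cutoff."""

    patient_id: str
    index_code: str
    effective_followup: str | None
    score: PairScore | None
    flagged: bool
    flag_reason: Literal[
        "scored", "no_followup_assumed_unchanged", "skipped_unknown_code"
    ]
    reference_label: bool | None = None
    rating_category: str | None = None


def crosses_cutoff(value: float, algorithm: str, cutoff: float) -> bool:
    """Flagging rule: >= cutoff for distances, <= cutoff for similarities."""
    return value >= cutoff if is_distance(algorithm) else value <= cutoff


def screen_pairs(
    pairs: Iterable[DiagnosisPair],
    t: Taxonomy,
    algorithm: str = "steps",
    cutoff: float = 2.0,
    policy: Literal["error", "skip"] = "error",
    w: EdgeWeightScheme | None = None,
    p: LiParameters | None = None,
) -> list[ScreeningRecord]:
    """Score and flag every pair, one record per pair in input order.

    ``policy`` controls unknown codes: ``"error"`` raises
    :class:`UnknownCodeError` naming the patient; ``"skip"`` emits an
    unscored record with reason ``skipped_unknown_code`` (excluded from
    downstream validation counts).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if not math.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    w = w or EdgeWeightScheme()
    p = p or LiParameters()
    dist = is_distance(algorithm)

    records: list[ScreeningRecord] = []
    for pair in pairs:
        if not pair.followup_codes:
            records.append(
                ScreeningRecord(
                    patient_id=pair.patient_id,
                    index_code=pair.index_code,
                    effective_followup=None,
                    score=None,
                    flagged=False,
                    flag_reason="no_followup_assumed_unchanged",
                    reference_label=pair.reference_label,
                    rating_category=pair.rating_category,
                )
            )
            continue
        try:
            codes = [pair.index_code, *pair.followup_codes]
            for code in codes:
                if code == ROOT_CODE:
                    raise UnknownCodeError(
                        f"patient {pair.patient_id!r}: the virtual root is not "
                        "a diagnosis"
                    )
                t.node(code)
            scores = [
                score_pair(t, pair.index_code, fu, w, p)
                for fu in pair.followup_codes
            ]
        except UnknownCodeError as exc:
            if policy == "error":
                raise UnknownCodeError(
                    f"patient {pair.patient_id!r}: {exc}"
                ) from None
            records.append(
                ScreeningRecord(
                    patient_id=pair.patient_id,
                    index_code=pair.index_code,
                    effective_followup=None,
                    score=None,
                    flagged=False,
                    flag_reason="skipped_unknown_code",
                    reference_label=pair.reference_label,
                    rating_category=pair.rating_category,
                )
            )
            continue
        # effective follow-up = minimal discrepancy; ties -> first listed
        keyed = [s.value(algorithm) for s in scores]
        best = min(range(len(keyed)), key=lambda i: keyed[i]) if dist else min(
            range(len(keyed)), key=lambda i: -keyed[i]
        )
        score = scores[best]
        records.append(
            ScreeningRecord(
                patient_id=pair.patient_id,
                index_code=pair.index_code,
                effective_followup=pair.followup_codes[best],
                score=score,
                flagged=crosses_cutoff(score.value(algorithm), algorithm, cutoff),
                flag_reason="scored",
                reference_label=pair.reference_label,
                rating_category=pair.rating_category,
            )
        )
    return records


# ---------------------------------------------------------------------------
# pairs CSV dialect


def _parse_bool(raw: str, patient_id: str) -> bool | None:
    s = raw.strip().lower()
    if s == "":
        return None
    if s == "true":
        return True
    if s == "false":
        return False
    raise FormatError(
        f"patient {patient_id!r}: malformed reference_label {raw!r} "
        "(expected true/false/empty)"
    )


def read_pairs(source) -> list[DiagnosisPair]:
    """Parse the pairs CSV dialect into :class:`DiagnosisPair` objects.

    Columns: ``patient_id, index_code, followup_codes, reference_label,
    rating_category``. Follow-up codes are semicolon-separated; an empty
    cell means no documented follow-up care. Codes are normalized on read.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = set(PAIRS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"pairs CSV missing required columns {sorted(missing)}")
    pairs = []
    for row in df.itertuples(index=False):
        pid = str(row.patient_id)
        followups = tuple(
            normalize_code(c) for c in str(row.followup_codes).split(";") if c.strip()
        )
        rating = str(row.rating_category).strip() or None
        pairs.append(
            DiagnosisPair(
                patient_id=pid,
                index_code=normalize_code(row.index_code),
                followup_codes=followups,
                reference_label=_parse_bool(str(row.reference_label), pid),
                rating_category=rating,
            )
        )
    return pairs


def pairs_to_frame(pairs: Sequence[DiagnosisPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in pairs],
            "index_code": [p.index_code for p in pairs],
            "followup_codes": [";".join(p.followup_codes) for p in pairs],
            "reference_label": [
                "" if p.reference_label is None else str(p.reference_label).lower()
                for p in pairs
            ],
            "rating_category": [p.rating_category or "" for p in pairs],
        }
    )


def write_pairs(pairs: Sequence[DiagnosisPair], destination=None) -> str:
    """Serialize pairs to the CSV dialect; returns the CSV text."""
    text = pairs_to_frame(pairs).to_csv(index=False)
    if destination is not None:
        with open(destination, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# records CSV dialect


def records_to_frame(records: Sequence[ScreeningRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        s = r.score
        rows.append(
            {
                "patient_id": r.patient_id,
                "index_code": r.index_code,
                "effective_followup": r.effective_followup or "",
                "steps": "" if s is None else s.steps,
                "weighted": "" if s is None else repr(s.weighted),
                "wu_palmer": "" if s is None else repr(s.wu_palmer),
                "li": "" if s is None else repr(s.li),
                "lca_depth": "" if s is None else s.lca_depth,
                "lca_code": "" if s is None else s.lca_code,
                "flagged": str(r.flagged).lower(),
                "flag_reason": r.flag_reason,
                "reference_label": ""
                if r.reference_label is None
                else str(r.reference_label).lower(),
                "rating_category": r.rating_category or "",
            }
        )
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def write_records(records: Sequence[ScreeningRecord], destination=None) -> str:
    """Serialize screening records to CSV (deterministic column order)."""
    text = records_to_frame(records).to_csv(index=False)
    if destination is not None:
        with open(destination, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
    return text


def read_records(source) -> list[ScreeningRecord]:
    """Read back a records CSV written by :func:`write_records`."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"records CSV missing required columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        pid = str(row.patient_id)
        if str(row.steps).strip() == "":
            score = None
        else:
            score = PairScore(
                steps=int(row.steps),
                weighted=float(row.weighted),
                wu_palmer=float(row.wu_palmer),
                li=float(row.li),
                lca_depth=int(row.lca_depth),
                lca_code=str(row.lca_code),
            )
        records.append(
            ScreeningRecord(
                patient_id=pid,
                index_code=str(row.index_code),
                effective_followup=str(row.effective_followup) or None,
                score=score,
                flagged=_parse_bool(str(row.flagged), pid) or False,
                flag_reason=str(row.flag_reason),  # type: ignore[arg-type]
                reference_label=_parse_bool(str(row.reference_label), pid),
                rating_category=str(row.rating_category).strip() or None,
            )
        )
    return records
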