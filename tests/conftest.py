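"""Shared fixtures: taxonomies and record builders used across the suite."""

from __future__ import annotations

import pytest

from icddx import PairScore, ScreeningRecord, load_builtin_taxonomy, load_taxonomy


@pytest.fixture(scope="session")
def mini():
    """The packaged four-chapter miniature taxonomy (65 nodes, depth 5)."""
    return load_builtin_taxonomy()


def balanced31_tsv(shuffle_seed: int | None = None) -> str:
    """A balanced depth-4 tree: 2 chapters x 2 blocks x 2 categories x 2
    subcategories = 31 nodes including the implicit root."""
    rows = []
    for c in range(1, 3):
        ch = f"C{c}"
        rows.append(f"{ch}\tROOT\tchapter\tchapter {c}")
        for b in range(1, 3):
            bl = f"{ch}B{b}"
            rows.append(f"{bl}\t{ch}\tblock\tblock {c}.{b}")
            for k in range(1, 3):
                cat = f"{bl}X{k}"
                rows.append(f"{cat}\t{bl}\tcategory\tcategory {c}.{b}.{k}")
                for s in range(1, 3):
                    sub = f"{cat}S{s}"
                    rows.append(f"{sub}\t{cat}\tsubcategory4\tsub {c}.{b}.{k}.{s}")
    if shuffle_seed is not None:
        import random

        random.Random(shuffle_seed).shuffle(rows)
    return "code\tparent\tlevel\tlabel\n" + "\n".join(rows) + "\n"


@pytest.fixture(scope="session")
def balanced31():
    return load_taxonomy(balanced31_tsv())


def make_record(
    patient_id: str,
    steps: float,
    label: bool | None,
    category: str | None = None,
    weighted: float | None = None,
    wu_palmer: float = 0.0,
    li: float = 0.0,
) -> ScreeningRecord:
    """A labeled screening record with a hand-set score, for validation tests."""
    return ScreeningRecord(
        patient_id=patient_id,
        index_code="X",
        effective_followup="Y",
        score=PairScore(
            steps=int(steps),
            weighted=float(weighted if weighted is not None else steps),
            wu_palmer=wu_palmer,
            li=li,
            lca_depth=0,
            lca_code="ROOT",
        ),
        flagged=False,
        flag_reason="scored",
        reference_label=label,
        rating_category=category,
    )


def make_records(scores, labels, categories=None):
    cats = categories or [None] * len(scores)
    return [
        make_record(f"P{i}", s, bool(l), c)
        for i, (s, l, c) in enumerate(zip(scores, labels, cats))
    ]
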