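"""Seeded synthetic cohorts with the study's rating structure.

The validation cohort this package emulates contains 1,204 ED patients
whose index/follow-up diagnosis pairs were expert-rated into five
categories: *identical*, *precision* (a refinement of the index diagnosis),
*complication* (a new, unforeseeable diagnosis), *diagnostically different*
and *hierarchically different*; the last two constitute an expert-confirmed
discrepancy (101/1,204 = 8.4%). The five rating counts (932/98/65/89/12)
sum to 1,196: eight pairs carry no expert rating, and the generator
reproduces them as unlabeled pairs.

Each rating category is mapped to concrete tree relationships (this mapping
is a modeling choice — real per-category distance distributions are not
published — and is fully configurable via ``templates``):

* identical — mostly the same code (0 steps); a small fraction
  (14/932 by default) are *medically* identical diagnoses coded to a
  sibling subcategory (2 steps), the cases a step-count trigger wrongly
  flags even though experts call them identical.
* precision — ancestor/descendant refinement, 1 or 2 steps (10/88 split so
  that 88 precision pairs sit at >= 2 steps).
* complication — same chapter, different block (4 or 6 steps); 5 of 65
  follow-up letters still list the index diagnosis alongside the new one,
  so their effective distance under the min-over-follow-ups rule is 0.
* diagnostically different — cross-chapter pairs at 6, 8 or 10 steps.
* hierarchically different — cross-chapter pairs at mismatched depths
  (5, 7 or 9 steps).

``mode="exact"`` allocates category and template counts deterministically
by largest remainder, so the printed marginals (932/98/65/89/12 ratings,
101 discrepant, 303 without follow-up) are reproduced exactly at n=1,204;
``mode="sampled"`` draws categories i.i.d. for distributional tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import GenerationError
from .screening import DiagnosisPair, DISCREPANT_CATEGORIES, RATING_CATEGORIES
from .taxonomy import CodeLevel, Taxonomy

#: Pseudo-category for pairs without an expert rating (label None).
UNRATED = "unrated"

#: Default category weights: the study's integer counts (sum 1204).
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "identical": 932,
    "precision": 98,
    "complication": 65,
    "diagnostically_different": 89,
    "hierarchically_different": 12,
    UNRATED: 8,
}

#: (template kind, target effective steps, weight) per category.
DEFAULT_TEMPLATES: dict[str, tuple[tuple[str, int, float], ...]] = {
    "identical": (("same_code", 0, 918.0), ("sibling_recode", 2, 14.0)),
    "precision": (("refine", 1, 10.0), ("refine", 2, 88.0)),
    "complication": (
        ("cross_block", 4, 30.0),
        ("cross_block", 6, 30.0),
        ("echo", 0, 5.0),
    ),
    "diagnostically_different": (
        ("cross_chapter", 6, 1.0),
        ("cross_chapter", 8, 1.0),
        ("cross_chapter", 10, 1.0),
    ),
    "hierarchically_different": (
        ("cross_chapter_skew", 5, 1.0),
        ("cross_chapter_skew", 7, 1.0),
        ("cross_chapter_skew", 9, 1.0),
    ),
    UNRATED: (("same_code", 0, 1.0),),
}

#: Default share of pairs with no documented follow-up care (303/1204).
DEFAULT_MISSING_FOLLOWUP = 303 / 1204


def largest_remainder(n: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Allocate n units proportionally to weights; ties by insertion order."""
    total = float(sum(weights.values()))
    if total <= 0:
        raise ValueError("weights must have positive sum")
    quotas = {k: n * w / total for k, w in weights.items()}
    counts = {k: math.floor(q) for k, q in quotas.items()}
    leftover = n - sum(counts.values())
    by_fraction = sorted(weights, key=lambda k: -(quotas[k] - counts[k]))
    for k in by_fraction[:leftover]:
        counts[k] += 1
    return counts


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``proportions`` may name the five rating categories (summing to 1); when
    None the study's integer counts — including 8 unrated pairs — are used
    as weights, which is exact at n=1204. ``templates`` overrides the
    category-to-tree-relationship mapping.
    """

    n: int = 1204
    proportions: Mapping[str, float] | None = None
    seed: int = 7
    mode: str = "exact"  # "exact" | "sampled"
    templates: Mapping[str, tuple[tuple[str, int, float], ...]] = field(
        default_factory=lambda: DEFAULT_TEMPLATES
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        if self.mode not in ("exact", "sampled"):
            raise ValueError(f"mode must be 'exact' or 'sampled', got {self.mode!r}")
        if self.proportions is not None:
            unknown = set(self.proportions) - set(RATING_CATEGORIES) - {UNRATED}
            if unknown:
                raise ValueError(f"unknown categories in proportions: {unknown}")
            if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
                raise ValueError("proportions must sum to 1 within 1e-9")

    @property
    def category_weights(self) -> dict[str, float]:
        if self.proportions is None:
            return dict(DEFAULT_CATEGORY_WEIGHTS)
        return dict(self.proportions)


# ---------------------------------------------------------------------------
# template pools


def _build_pools(
    t: Taxonomy,
) -> dict[tuple[str, int], list[tuple[str, tuple[str, ...]]]]:
    """Enumerate (index_code, followup_codes) candidates for every template."""
    chapters = t.codes_at_level(CodeLevel.CHAPTER)
    if len(chapters) < 2:
        raise GenerationError("taxonomy must have at least 2 chapters")
    levels = {
        lvl: t.codes_at_level(lvl)
        for lvl in (
            CodeLevel.BLOCK,
            CodeLevel.CATEGORY,
            CodeLevel.SUBCATEGORY4,
            CodeLevel.SUBCATEGORY5,
        )
    }
    if not levels[CodeLevel.SUBCATEGORY4]:
        raise GenerationError("taxonomy must reach depth 4")
    chap = {c: t.chapter_of(c) for n in levels.values() for c in n}

    def block_of(code: str) -> str:
        for anc in t.ancestors(code):
            if t.node(anc).level == CodeLevel.BLOCK:
                return anc
        raise GenerationError(f"{code!r} has no block ancestor")

    def cross_chapter(xs: list[str], ys: list[str]):
        return [(a, (b,)) for a in xs for b in ys if chap[a] != chap[b]]

    def cross_block_same_chapter(xs: list[str]):
        return [
            (a, (b,))
            for a in xs
            for b in xs
            if a != b and chap[a] == chap[b] and block_of(a) != block_of(b)
        ]

    sub4 = levels[CodeLevel.SUBCATEGORY4]
    sub5 = levels[CodeLevel.SUBCATEGORY5]
    cats = levels[CodeLevel.CATEGORY]
    blocks = levels[CodeLevel.BLOCK]

    siblings = [
        (a, (b,))
        for a in sub4
        for b in sub4
        if a != b and t.parent(a) == t.parent(b)
    ]
    refine1 = [(t.parent(s), (s,)) for s in sub4] + [(t.parent(s), (s,)) for s in sub5]
    refine2 = [(t.parent(t.parent(s)), (s,)) for s in sub5]
    cb6 = cross_block_same_chapter(sub4)
    pools: dict[tuple[str, int], list[tuple[str, tuple[str, ...]]]] = {
        ("same_code", 0): [(s, (s,)) for s in sub4],
        ("sibling_recode", 2): siblings,
        ("refine", 1): refine1,
        ("refine", 2): refine2,
        ("cross_block", 4): cross_block_same_chapter(cats),
        ("cross_block", 6): cb6,
        # follow-up letter still lists the index diagnosis -> effective 0
        ("echo", 0): [(a, (b, a)) for a, (b,) in cb6],
        ("cross_chapter", 6): cross_chapter(cats, cats),
        ("cross_chapter", 8): cross_chapter(sub4, sub4),
        ("cross_chapter", 10): cross_chapter(sub5, sub5),
        ("cross_chapter_skew", 5): cross_chapter(blocks, cats),
        ("cross_chapter_skew", 7): cross_chapter(cats, sub4),
        ("cross_chapter_skew", 9): cross_chapter(sub4, sub5),
    }
    return pools


def _draw(
    pools, kind: str, steps: int, count: int, rng: np.random.Generator
) -> list[tuple[str, tuple[str, ...], int]]:
    pool = pools.get((kind, steps))
    if not pool:
        raise GenerationError(
            f"taxonomy cannot realize template {kind!r} at {steps} steps"
        )
    picks = rng.integers(0, len(pool), size=count)
    out = []
    for i in picks:
        index, followups = pool[int(i)]
        if kind == "cross_chapter_skew" and rng.random() < 0.5:
            # either diagnosis may be the coarser one
            index, followups = followups[0], (index,)
        out.append((index, followups, steps))
    return out


def generate_cohort(
    spec: CohortSpec, t: Taxonomy, with_targets: bool = False
) -> list[DiagnosisPair] | list[tuple[DiagnosisPair, int]]:
    """Build a seeded cohort of :class:`DiagnosisPair` over taxonomy ``t``.

    With ``with_targets=True`` each pair is returned together with its
    construction target: the effective step distance the pair was built to
    have (after the min-over-follow-ups rule).
    """
    rng = np.random.default_rng(spec.seed)
    pools = _build_pools(t)
    weights = spec.category_weights

    if spec.mode == "exact":
        cat_counts = largest_remainder(spec.n, weights)
    else:
        names = list(weights)
        probs = np.array([weights[k] for k in names], dtype=float)
        draws = rng.choice(len(names), size=spec.n, p=probs / probs.sum())
        cat_counts = {k: int((draws == i).sum()) for i, k in enumerate(names)}

    built: list[tuple[str, str, tuple[str, ...], int]] = []
    for category, count in cat_counts.items():
        if count == 0:
            continue
        templates = spec.templates.get(category)
        if not templates:
            raise GenerationError(f"no templates defined for category {category!r}")
        tmpl_weights = {f"{k}@{s}": w for k, s, w in templates}
        if spec.mode == "exact":
            tmpl_counts = largest_remainder(count, tmpl_weights)
        else:
            names = list(tmpl_weights)
            probs = np.array([tmpl_weights[k] for k in names], dtype=float)
            draws = rng.choice(len(names), size=count, p=probs / probs.sum())
            tmpl_counts = {k: int((draws == i).sum()) for i, k in enumerate(names)}
        for (kind, steps, _w), key in zip(templates, tmpl_counts):
            k = tmpl_counts[key]
            for index, followups, target in _draw(pools, kind, steps, k, rng):
                built.append((category, index, followups, target))

    order = rng.permutation(len(built))
    results: list[tuple[DiagnosisPair, int]] = []
    for i, j in enumerate(order):
        category, index, followups, target = built[int(j)]
        unrated = category == UNRATED
        pair = DiagnosisPair(
            patient_id=f"P{i + 1:04d}",
            index_code=index,
            followup_codes=followups,
            reference_label=None if unrated else category in DISCREPANT_CATEGORIES,
            rating_category=None if unrated else category,
        )
        results.append((pair, target))
    if with_targets:
        return results
    return [pair for pair, _ in results]


def degrade_cohort(
    pairs: Sequence[DiagnosisPair],
    fraction_missing_followup: float = DEFAULT_MISSING_FOLLOWUP,
    seed: int = 0,
) -> list[DiagnosisPair]:
    """Remove follow-up codes from a fraction of non-discrepant pairs.

    Models patients discharged from the ED with no subsequent documented
    care (default 303/1204). Pairs whose follow-up already equals the index
    diagnosis are preferred — a patient who needed no follow-up care is one
    whose diagnosis did not evolve. Labels are unchanged.
    """
    if not 0.0 <= fraction_missing_followup <= 1.0:
        raise ValueError("fraction_missing_followup must be in [0, 1]")
    n_remove = round(fraction_missing_followup * len(pairs))
    eligible = [i for i, p in enumerate(pairs) if p.reference_label is not True]
    if n_remove > len(eligible):
        raise GenerationError(
            f"cannot remove follow-up from {n_remove} pairs: only "
            f"{len(eligible)} non-discrepant pairs are eligible"
        )
    rng = np.random.default_rng(seed)
    unchanged = [
        i for i in eligible if pairs[i].followup_codes == (pairs[i].index_code,)
    ]
    other = [i for i in eligible if i not in set(unchanged)]
    ordered = list(rng.permutation(unchanged)) + list(rng.permutation(other))
    chosen = set(int(i) for i in ordered[:n_remove])
    out = []
    for i, p in enumerate(pairs):
        if i in chosen:
            p = DiagnosisPair(
                patient_id=p.patient_id,
                index_code=p.index_code,
                followup_codes=(),
                reference_label=p.reference_label,
                rating_category=p.rating_category,
            )
        out.append(p)
    return out
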