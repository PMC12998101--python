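"""Diagnosis distance and similarity algorithms on the ICD-10 tree.

Four algorithms quantify how far apart two diagnoses sit in the hierarchy.
With ``l`` the number of edges on the unique tree path between codes *a* and
*b*, and ``h`` the depth of their lowest common ancestor (LCA):

``steps``
    Unweighted path length ``l = depth(a) + depth(b) - 2 h``. A distance.
``weighted``
    Path length with per-level edge weights; by default an edge whose deeper
    endpoint is a chapter (i.e. a root-to-chapter transition) costs 2.0 and
    every other edge 1.0, so crossing between chapters is penalized.
    A distance.
``wu_palmer``
    ``2 h / (depth(a) + depth(b))`` — depth-normalized similarity in [0, 1].
``li``
    ``exp(-alpha * l) * tanh(beta * h)`` — a nonlinear blend of path length
    and ancestor depth designed to track human similarity judgements.
    Similarity in [0, 1]; defaults alpha = 0.2, beta = 0.6.

Distances grow with discrepancy; similarities shrink. The screening and
validation layers map this polarity explicitly per algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .taxonomy import CodeLevel, Taxonomy

#: Canonical algorithm names for CLI/config use.
DISTANCE_ALGORITHMS = ("steps", "weighted")
SIMILARITY_ALGORITHMS = ("wu_palmer", "li")
ALGORITHMS = DISTANCE_ALGORITHMS + SIMILARITY_ALGORITHMS


def is_distance(algorithm: str) -> bool:
    """True for distance-polarity algorithms (higher = more discrepant)."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return algorithm in DISTANCE_ALGORITHMS


@dataclass(frozen=True)
class EdgeWeightScheme:
    """Per-level edge weights, keyed by the deeper endpoint of each edge."""

    weights: Mapping[CodeLevel, float] = field(
        default_factory=lambda: {
            CodeLevel.CHAPTER: 2.0,
            CodeLevel.BLOCK: 1.0,
            CodeLevel.CATEGORY: 1.0,
            CodeLevel.SUBCATEGORY4: 1.0,
            CodeLevel.SUBCATEGORY5: 1.0,
        }
    )

    def __post_init__(self) -> None:
        for level, w in self.weights.items():
            if not w > 0:
                raise ValueError(f"edge weight for {level.name} must be > 0, got {w}")

    def weight(self, deeper_level: CodeLevel) -> float:
        return float(self.weights.get(deeper_level, 1.0))

    @classmethod
    def unit(cls) -> "EdgeWeightScheme":
        return cls(weights={})


@dataclass(frozen=True)
class LiParameters:
    """Constants of the Li similarity: path-length decay and depth saturation."""

    alpha: float = 0.2
    beta: float = 0.6

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")


@dataclass(frozen=True)
class PairScore:
    """All four algorithm outputs plus path diagnostics for one code pair."""

    steps: int
    weighted: float
    wu_palmer: float
    li: float
    lca_depth: int
    lca_code: str

    def value(self, algorithm: str) -> float:
        if algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        return float(getattr(self, algorithm))


def path_steps(t: Taxonomy, a: str, b: str) -> int:
    """Number of edges on the unique tree path between two codes."""
    lca = t.lowest_common_ancestor(a, b)
    return t.depth(a) + t.depth(b) - 2 * t.depth(lca)


def weighted_path(
    t: Taxonomy, a: str, b: str, w: EdgeWeightScheme | None = None
) -> float:
    """Sum of level weights along the path a -> LCA -> b."""
    w = w or EdgeWeightScheme()
    lca = t.lowest_common_ancestor(a, b)
    total = 0.0
    for end in (a, b):
        code = end
        while code != lca:
            total += w.weight(t.node(code).level)
            code = t.parent(code)
    return total


def wu_palmer(t: Taxonomy, a: str, b: str) -> float:
    """``2 h / (depth(a) + depth(b))``; root vs root is 1 by convention."""
    da, db = t.depth(a), t.depth(b)
    if da + db == 0:
        return 1.0
    h = t.depth(t.lowest_common_ancestor(a, b))
    return 2.0 * h / (da + db)


def li_similarity(
    t: Taxonomy, a: str, b: str, p: LiParameters | None = None
) -> float:
    """``exp(-alpha l) * tanh(beta h)``; 0 whenever the LCA is the root."""
    p = p or LiParameters()
    l = path_steps(t, a, b)
    h = t.depth(t.lowest_common_ancestor(a, b))
    return math.exp(-p.alpha * l) * math.tanh(p.beta * h)


def score_pair(
    t: Taxonomy,
    a: str,
    b: str,
    w: EdgeWeightScheme | None = None,
    p: LiParameters | None = None,
) -> PairScore:
    """Bundle all four algorithm outputs and path diagnostics for one pair."""
    w = w or EdgeWeightScheme()
    p = p or LiParameters()
    lca = t.lowest_common_ancestor(a, b)
    h = t.depth(lca)
    l = t.depth(a) + t.depth(b) - 2 * h
    return PairScore(
        steps=l,
        weighted=weighted_path(t, a, b, w),
        wu_palmer=wu_palmer(t, a, b),
        li=math.exp(-p.alpha * l) * math.tanh(p.beta * h),
        lca_depth=h,
        lca_code=lca,
    )
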