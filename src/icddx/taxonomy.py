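"""Rooted-tree model of the ICD-10 code hierarchy.

ICD-10 organizes diagnoses on a branching tree: chapters (e.g. *Diseases of
the respiratory system*) contain blocks (``J09-J18``), blocks contain
three-character categories (``J18``), and categories contain four- and
five-character subcategories (``J18.9``). A single virtual root joins the
chapters so that paths between codes in different chapters are defined.

This module provides the tree container plus the depth, ancestor,
lowest-common-ancestor and serialization primitives that every similarity
algorithm consumes. Tree queries are total functions over known codes:
an unknown code always raises :class:`~icddx.errors.UnknownCodeError`;
lenient handling (skip with a warning) is a screening-layer policy.
"""

from __future__ import annotations

import csv
import enum
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

from .errors import (
    DuplicateCodeError,
    FormatError,
    InvalidCodeError,
    LevelInconsistencyError,
    MissingParentError,
    UnknownCodeError,
)

ROOT_CODE = "ROOT"

_WS_RE = re.compile(r"\s+")


class CodeLevel(enum.IntEnum):
    """Hierarchy level of a node; the integer value is its tree depth."""

    ROOT = 0
    CHAPTER = 1
    BLOCK = 2
    CATEGORY = 3
    SUBCATEGORY4 = 4
    SUBCATEGORY5 = 5

    @property
    def rank(self) -> int:
        return int(self)

    @classmethod
    def from_name(cls, name: str) -> "CodeLevel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise FormatError(f"unknown taxonomy level {name!r}") from None


#: Levels that may appear in a taxonomy TSV (the root row is implicit).
FILE_LEVELS = (
    CodeLevel.CHAPTER,
    CodeLevel.BLOCK,
    CodeLevel.CATEGORY,
    CodeLevel.SUBCATEGORY4,
    CodeLevel.SUBCATEGORY5,
)


def normalize_code(raw: str) -> str:
    """Normalize an ICD-10 code string: uppercase, dot removed, no whitespace.

    Idempotent; ``"a00.0"`` and ``"A000"`` normalize to the same code, which
    matters for Swiss sources that mix both spellings.

    Raises
    ------
    InvalidCodeError
        If the input is empty or whitespace-only.
    """
    if raw is None:
        raise InvalidCodeError("code is None")
    code = _WS_RE.sub("", str(raw))
    if not code:
        raise InvalidCodeError(f"empty code string {raw!r}")
    return code.replace(".", "").upper()


@dataclass(frozen=True)
class TaxonomyNode:
    """One position in the code tree."""

    code: str
    label: str
    level: CodeLevel
    parent_code: str | None  # None only for the root


@dataclass
class Taxonomy:
    """A rooted ICD-10-like code tree with O(depth) ancestor queries.

    Invariants (enforced at load time): codes are unique; every non-root
    node has exactly one parent whose level rank is one less than its own;
    walking parent links from any node reaches the root in exactly
    ``level.rank`` steps.
    """

    nodes: dict[str, TaxonomyNode]
    root_code: str = ROOT_CODE
    _diameter: int | None = field(default=None, repr=False, compare=False)

    # -- basic queries -------------------------------------------------

    def __contains__(self, code: str) -> bool:
        return code in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, code: str) -> TaxonomyNode:
        try:
            return self.nodes[code]
        except KeyError:
            raise UnknownCodeError(f"code {code!r} not in taxonomy") from None

    def depth(self, code: str) -> int:
        """Number of edges from ``code`` to the root (= its level rank)."""
        return self.node(code).level.rank

    def parent(self, code: str) -> str | None:
        return self.node(code).parent_code

    def ancestors(self, code: str) -> list[str]:
        """Path from ``code`` up to and including the root."""
        path = [code]
        node = self.node(code)
        while node.parent_code is not None:
            path.append(node.parent_code)
            node = self.node(node.parent_code)
        return path

    def lowest_common_ancestor(self, a: str, b: str) -> str:
        """Deepest node lying on both root paths; symmetric, lca(a, a) = a."""
        na, nb = self.node(a), self.node(b)
        ca, cb = a, b
        # climb the deeper one first, then climb both in lock step
        da, db = na.level.rank, nb.level.rank
        while da > db:
            ca = self.nodes[ca].parent_code
            da -= 1
        while db > da:
            cb = self.nodes[cb].parent_code
            db -= 1
        while ca != cb:
            ca = self.nodes[ca].parent_code
            cb = self.nodes[cb].parent_code
        return ca

    def children(self, code: str) -> list[str]:
        self.node(code)
        return sorted(n.code for n in self.nodes.values() if n.parent_code == code)

    def codes_at_level(self, level: CodeLevel) -> list[str]:
        return sorted(n.code for n in self.nodes.values() if n.level == level)

    def chapter_of(self, code: str) -> str | None:
        """Chapter ancestor of a code (itself if a chapter, None for root)."""
        for anc in self.ancestors(code):
            if self.nodes[anc].level == CodeLevel.CHAPTER:
                return anc
        return None

    def diameter(self) -> int:
        """Longest unweighted path between any two nodes (cached)."""
        if self._diameter is None:
            best = 0
            ranks = {c: n.level.rank for c, n in self.nodes.items()}
            codes = list(self.nodes)
            for i, a in enumerate(codes):
                for b in codes[i + 1 :]:
                    lca = self.lowest_common_ancestor(a, b)
                    d = ranks[a] + ranks[b] - 2 * ranks[lca]
                    if d > best:
                        best = d
            self._diameter = best
        return self._diameter

    # -- serialization -------------------------------------------------

    def to_tsv(self) -> str:
        """Serialize to the taxonomy TSV dialect (root row omitted)."""
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
        writer.writerow(["code", "parent", "level", "label"])
        for node in sorted(self.nodes.values(), key=lambda n: (n.level.rank, n.code)):
            if node.code == self.root_code:
                continue
            writer.writerow(
                [node.code, node.parent_code, node.level.name.lower(), node.label]
            )
        return buf.getvalue()


def load_taxonomy(source: str | Iterable[str]) -> Taxonomy:
    """Parse a taxonomy from TSV content (a string or an iterable of lines).

    Dialect: UTF-8, tab-separated, header ``code  parent  level  label``;
    ``level`` one of chapter/block/category/subcategory4/subcategory5; the
    root row is implicit (chapters may name ``ROOT`` or leave parent empty);
    lines starting with ``#`` are comments. Row order is irrelevant —
    forward references to parents are resolved after the whole file is read.
    """
    if isinstance(source, str):
        lines: Iterator[str] = iter(io.StringIO(source))
    else:
        lines = iter(source)

    rows = [
        line.rstrip("\n")
        for line in lines
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not rows:
        raise FormatError("taxonomy source is empty")
    reader = csv.reader(rows, delimiter="\t")
    header = [h.strip().lower() for h in next(reader)]
    required = ("code", "parent", "level", "label")
    if not set(required).issubset(header):
        raise FormatError(
            f"taxonomy header must contain {required}, got {tuple(header)}"
        )
    idx = {name: header.index(name) for name in required}

    nodes: dict[str, TaxonomyNode] = {
        ROOT_CODE: TaxonomyNode(ROOT_CODE, "ICD-10 root", CodeLevel.ROOT, None)
    }
    for lineno, row in enumerate(reader, start=2):
        if len(row) < len(header):
            raise FormatError(f"taxonomy line {lineno}: expected {len(header)} fields")
        code = normalize_code(row[idx["code"]])
        level = CodeLevel.from_name(row[idx["level"]])
        if level not in FILE_LEVELS:
            raise FormatError(f"taxonomy line {lineno}: level {level.name} not allowed")
        raw_parent = row[idx["parent"]].strip()
        parent = normalize_code(raw_parent) if raw_parent else ROOT_CODE
        if code in nodes:
            raise DuplicateCodeError(f"duplicate code {code!r} (line {lineno})")
        nodes[code] = TaxonomyNode(code, row[idx["label"]].strip(), level, parent)

    # resolve after full read so row order never matters
    for node in nodes.values():
        if node.parent_code is None:
            continue
        parent = nodes.get(node.parent_code)
        if parent is None:
            raise MissingParentError(
                f"code {node.code!r} references unknown parent {node.parent_code!r}"
            )
        if parent.level.rank != node.level.rank - 1:
            raise LevelInconsistencyError(
                f"code {node.code!r} has level {node.level.name} (rank "
                f"{node.level.rank}) but parent {parent.code!r} has rank "
                f"{parent.level.rank}; expected parent rank {node.level.rank - 1}"
            )
    return Taxonomy(nodes=nodes)


def read_taxonomy(path) -> Taxonomy:
    """Load a taxonomy from a TSV file on disk."""
    with open(path, "r", encoding="utf-8") as fh:
        return load_taxonomy(fh)


def load_builtin_taxonomy() -> Taxonomy:
    """The miniature four-chapter ICD-10-like taxonomy shipped with icddx."""
    text = (
        resources.files("icddx").joinpath("data/mini_icd10.tsv").read_text("utf-8")
    )
    return load_taxonomy(text)
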