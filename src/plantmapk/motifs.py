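"""Degenerate consensus-motif notation: parsing and scanning.

The notation is the hyphen-separated kinase-literature style: single
residue letters, alternatives joined by ``/`` (``S/T``), and wildcards
``x`` or ``x_k`` for a run of ``k`` arbitrary residues.  An ``X``
(unknown) in a *sequence* matches nothing, wildcards included, so
low-quality stretches never produce motif calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

from .constants import AMINO_ACIDS

_AA = frozenset(AMINO_ACIDS)

CATEGORIES = (
    "nterm_txy",
    "nterm_secondary",
    "kinase_signature",
    "activation_loop",
    "cterm_postloop",
    "cd_site",
)


class PatternError(ValueError):
    """Raised for malformed consensus-pattern text."""


@dataclass(frozen=True)
class Residue:
    letter: str

    @property
    def width(self) -> int:
        return 1

    def accepts(self, ch: str) -> bool:
        return ch == self.letter


@dataclass(frozen=True)
class Alternative:
    letters: frozenset[str]

    @property
    def width(self) -> int:
        return 1

    def accepts(self, ch: str) -> bool:
        return ch in self.letters


@dataclass(frozen=True)
class Wildcard:
    repeat: int

    @property
    def width(self) -> int:
        return self.repeat

    def accepts(self, ch: str) -> bool:
        return ch in _AA  # any standard residue; 'X' excluded


Element = Union[Residue, Alternative, Wildcard]


@dataclass(frozen=True)
class ConsensusPattern:
    id: str
    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise PatternError(f"pattern {self.id!r}: no elements")

    @property
    def length(self) -> int:
        return sum(el.width for el in self.elements)

    @property
    def text(self) -> str:
        parts = []
        for el in self.elements:
            if isinstance(el, Residue):
                parts.append(el.letter)
            elif isinstance(el, Alternative):
                parts.append("/".join(sorted(el.letters)))
            else:
                parts.append("x" if el.repeat == 1 else f"x_{el.repeat}")
        return "-".join(parts)


@dataclass(frozen=True)
class PatternMatch:
    pattern_id: str
    start: int
    end: int
    matched: str


def parse_pattern(text: str, id: str | None = None) -> ConsensusPattern:
    """Parse hyphen-separated consensus text into a ConsensusPattern."""
    elements: list[Element] = []
    for token in text.strip().split("-"):
        if not token:
            raise PatternError(f"empty token in pattern {text!r}")
        if token == "x":
            elements.append(Wildcard(1))
        elif token.startswith("x_"):
            try:
                k = int(token[2:])
            except ValueError:
                raise PatternError(f"bad wildcard token {token!r}") from None
            if k < 1:
                raise PatternError(f"wildcard repeat must be >= 1, got {token!r}")
            elements.append(Wildcard(k))
        elif "/" in token:
            letters = frozenset(token.split("/"))
            if len(letters) < 2 or not letters <= _AA:
                raise PatternError(f"bad alternative token {token!r}")
            elements.append(Alternative(letters))
        elif len(token) == 1 and token in _AA:
            elements.append(Residue(token))
        else:
            raise PatternError(f"unknown token {token!r} in pattern {text!r}")
    return ConsensusPattern(id=id or text, elements=tuple(elements))


def _matches_at(pattern: ConsensusPattern, sequence: str, start: int) -> bool:
    pos = start
    for el in pattern.elements:
        for _ in range(el.width):
            if not el.accepts(sequence[pos]):
                return False
            pos += 1
    return True


def scan(pattern: ConsensusPattern, sequence: str) -> list[PatternMatch]:
    """All (possibly overlapping) matches of ``pattern``, sorted by start."""
    width = pattern.length
    out = []
    for start in range(len(sequence) - width + 1):
        if _matches_at(pattern, sequence, start):
            out.append(
                PatternMatch(
                    pattern_id=pattern.id,
                    start=start,
                    end=start + width,
                    matched=sequence[start : start + width],
                )
            )
    return out


@dataclass(frozen=True)
class LibraryEntry:
    category: str
    tag: str  # anchor slot, MAPK group, or "-"
    pattern: ConsensusPattern


class PatternLibrary:
    """A named collection of consensus patterns grouped by category."""

    def __init__(self, entries: Iterable[LibraryEntry]):
        self.entries = list(entries)
        self._by_category: dict[str, list[LibraryEntry]] = {}
        for entry in self.entries:
            self._by_category.setdefault(entry.category, []).append(entry)

    @property
    def categories(self) -> list[str]:
        return list(self._by_category)

    def category(self, name: str) -> list[LibraryEntry]:
        if name not in self._by_category:
            raise KeyError(f"unknown pattern category {name!r}")
        return self._by_category[name]

    def get(self, pattern_id: str) -> LibraryEntry:
        for entry in self.entries:
            if entry.pattern.id == pattern_id:
                return entry
        raise KeyError(f"no pattern with id {pattern_id!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PatternLibrary":
        entries = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise PatternError(f"library line needs 4 tab-separated fields: {line!r}")
            category, tag, pid, text = fields
            if category not in CATEGORIES:
                raise PatternError(f"unknown category {category!r}")
            entries.append(LibraryEntry(category, tag, parse_pattern(text, id=pid)))
        return cls(entries)


def default_library() -> PatternLibrary:
    """The shipped library reproducing the published motif inventory."""
    with resources.as_file(resources.files("plantmapk.data") / "patterns.tsv") as p:
        return PatternLibrary.from_tsv(p)


def scan_library(
    library: PatternLibrary,
    sequence: str,
    categories: Sequence[str] | None = None,
) -> dict[str, list[PatternMatch]]:
    """Per-category concatenation of scan() results over library patterns."""
    if categories is None:
        categories = library.categories
    out: dict[str, list[PatternMatch]] = {}
    for cat in categories:
        hits: list[PatternMatch] = []
        for entry in library.category(cat):
            hits.extend(scan(entry.pattern, sequence))
        hits.sort(key=lambda m: (m.start, m.pattern_id))
        if hits:
            out[cat] = hits
    return out
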