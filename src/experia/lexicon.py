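"""Sentiment seed lexicon and synonym/antonym neighbourhood.

The polarity of an adjective is resolved against a small seed list of
adjectives with known polarity, extended through a synonym/antonym graph:
a word inherits the polarity of a seeded synonym, or the opposite polarity
of a seeded antonym. The graph is loaded from a plain-text lexicon file
(the package's offline stand-in for WordNet); the shipped default lexicon
contains 30 polarity-labelled seed adjectives.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "Polarity",
    "SeedLexicon",
    "LexiconNeighborhood",
    "LexiconError",
    "load_lexicon",
    "default_lexicon",
    "lookup_polarity",
]


class LexiconError(ValueError):
    """Raised for malformed lexicon files or inconsistent seed entries."""


class Polarity(enum.Enum):
    """Three-way sentiment polarity of an opinion word or opinion."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEUTRAL = "neutral"

    @property
    def opposite(self) -> "Polarity":
        if self is Polarity.POSITIVE:
            return Polarity.NEGATIVE
        if self is Polarity.NEGATIVE:
            return Polarity.POSITIVE
        return Polarity.NEUTRAL

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class SeedLexicon:
    """Polarity-labelled word list.

    ``initial_size`` is frozen at construction: it records how many seeds
    the list started with and never changes as propagation grows
    ``entries``.
    """

    entries: dict[str, Polarity] = field(default_factory=dict)
    initial_size: int = -1

    def __post_init__(self) -> None:
        if self.initial_size < 0:
            self.initial_size = len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def polarity(self, word: str) -> Optional[Polarity]:
        return self.entries.get(word)

    def add(self, word: str, polarity: Polarity) -> None:
        """Add a word; re-adding with a conflicting polarity is an error."""
        existing = self.entries.get(word)
        if existing is not None and existing is not polarity:
            raise LexiconError(
                f"seed word {word!r} already has polarity {existing.value}, "
                f"cannot relabel as {polarity.value}"
            )
        self.entries[word] = polarity

    def copy(self) -> "SeedLexicon":
        return SeedLexicon(dict(self.entries), self.initial_size)

    def inverted(self) -> "SeedLexicon":
        """The lexicon with every polarity flipped (neutral stays)."""
        return SeedLexicon(
            {w: p.opposite for w, p in self.entries.items()}, self.initial_size
        )


@dataclass
class LexiconNeighborhood:
    """Symmetric synonym and antonym relations between words.

    Symmetry is enforced by closure at construction; a pair of words may
    not be related as both synonyms and antonyms.
    """

    synonyms: dict[str, set[str]] = field(default_factory=dict)
    antonyms: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._close(self.synonyms)
        self._close(self.antonyms)
        for word, syns in self.synonyms.items():
            clash = syns & self.antonyms.get(word, set())
            if clash:
                raise LexiconError(
                    f"words {sorted(clash)} are both synonym and antonym of {word!r}"
                )

    @staticmethod
    def _close(relation: dict[str, set[str]]) -> None:
        for word in list(relation):
            for other in list(relation[word]):
                if other == word:
                    relation[word].discard(word)
                    continue
                relation.setdefault(other, set()).add(word)

    def synonyms_of(self, word: str) -> frozenset[str]:
        return frozenset(self.synonyms.get(word, ()))

    def antonyms_of(self, word: str) -> frozenset[str]:
        return frozenset(self.antonyms.get(word, ()))

    def knows(self, word: str) -> bool:
        """Whether the word has any synonym or antonym entry at all."""
        return bool(self.synonyms.get(word)) or bool(self.antonyms.get(word))

    def vocabulary(self) -> frozenset[str]:
        return frozenset(self.synonyms) | frozenset(self.antonyms)


def _parse_polarity(text: str, lineno: int) -> Polarity:
    try:
        return Polarity(text.strip().lower())
    except ValueError:
        raise LexiconError(
            f"line {lineno}: unknown polarity {text.strip()!r} "
            "(expected positive/negative/neutral)"
        ) from None


def load_lexicon(path: str | Path) -> tuple[SeedLexicon, LexiconNeighborhood]:
    """Parse a lexicon file into a seed list and a neighbourhood.

    The file has three sections introduced by ``[seeds]``, ``[synonyms]``
    and ``[antonyms]``. Seed lines are ``word <whitespace> polarity``;
    relation lines are ``word: other, other, ...``. Blank lines and lines
    starting with ``#`` are ignored. All words are case-folded.

    Raises
    ------
    LexiconError
        On a malformed line (naming the line number) or a duplicate seed
        word with a conflicting polarity.
    """
    text = Path(path).read_text(encoding="utf-8")
    return parse_lexicon(text)


def parse_lexicon(text: str) -> tuple[SeedLexicon, LexiconNeighborhood]:
    seeds: dict[str, Polarity] = {}
    synonyms: dict[str, set[str]] = {}
    antonyms: dict[str, set[str]] = {}
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in ("seeds", "synonyms", "antonyms"):
                raise LexiconError(f"line {lineno}: unknown section {section!r}")
            continue
        if section is None:
            raise LexiconError(f"line {lineno}: content before any [section] header")
        if section == "seeds":
            parts = line.split()
            if len(parts) != 2:
                raise LexiconError(
                    f"line {lineno}: expected 'word polarity', got {line!r}"
                )
            word = parts[0].casefold()
            pol = _parse_polarity(parts[1], lineno)
            if word in seeds and seeds[word] is not pol:
                raise LexiconError(
                    f"line {lineno}: seed {word!r} relabelled "
                    f"{seeds[word].value} -> {pol.value}"
                )
            seeds[word] = pol
        else:
            if ":" not in line:
                raise LexiconError(
                    f"line {lineno}: expected 'word: w1, w2, ...', got {line!r}"
                )
            head, _, tail = line.partition(":")
            word = head.strip().casefold()
            if not word:
                raise LexiconError(f"line {lineno}: empty head word")
            others = {w.strip().casefold() for w in tail.split(",") if w.strip()}
            target = synonyms if section == "synonyms" else antonyms
            target.setdefault(word, set()).update(others)
    hood = LexiconNeighborhood(synonyms, antonyms)
    return SeedLexicon(seeds), hood


def default_lexicon() -> tuple[SeedLexicon, LexiconNeighborhood]:
    """The lexicon shipped with the package (30 seed adjectives)."""
    text = (
        resources.files("experia").joinpath("data/default_lexicon.txt").read_text()
    )
    return parse_lexicon(text)


def _majority(votes: Iterable[Polarity]) -> Optional[Polarity]:
    """Majority polarity of the votes; an exact tie resolves to neutral."""
    counts = Counter(votes)
    if not counts:
        return None
    pos = counts.get(Polarity.POSITIVE, 0)
    neg = counts.get(Polarity.NEGATIVE, 0)
    if pos > neg:
        return Polarity.POSITIVE
    if neg > pos:
        return Polarity.NEGATIVE
    return Polarity.NEUTRAL


def lookup_polarity(
    word: str, seeds: SeedLexicon, hood: LexiconNeighborhood
) -> Optional[Polarity]:
    """One-hop polarity lookup for a word.

    A seeded word keeps its seed polarity. Otherwise seeded synonyms are
    consulted first (same polarity), then seeded antonyms (opposite
    polarity); if several seeded neighbours disagree, the majority wins
    and an exact tie is neutral. Returns ``None`` when neither the word
    nor any one-hop neighbour is seeded.
    """
    word = word.casefold()
    direct = seeds.polarity(word)
    if direct is not None:
        return direct
    syn_votes = [
        seeds.entries[s] for s in sorted(hood.synonyms_of(word)) if s in seeds
    ]
    if syn_votes:
        return _majority(syn_votes)
    ant_votes = [
        seeds.entries[a].opposite
        for a in sorted(hood.antonyms_of(word))
        if a in seeds
    ]
    if ant_votes:
        return _majority(ant_votes)
    return None
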