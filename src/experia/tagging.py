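"""Tagged review documents and corpus I/O.

Reviews are represented as ordered sentences of ``(surface, pos)`` token
pairs over a deliberately coarse tagset — NOUN, ADJ, OTHER — which is all
the mining stage needs: nouns and noun phrases become candidate features,
adjectives become opinion-word candidates, everything else is scenery.

Corpora are read from JSON-lines, one review per line, either pre-tagged
(``{"doc_id": ..., "sentences": [[["pain", "NOUN"], ...], ...]}``) or raw
(``{"doc_id": ..., "text": "..."}``), in which case a small rule-based
tagger assigns coarse tags. The rule tagger is a convenience for raw
text; curated and generated corpora carry explicit tags.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from .lexicon import default_lexicon

__all__ = [
    "COARSE_TAGS",
    "TaggedToken",
    "TaggedDocument",
    "normalize_tag",
    "tag_text",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
]

COARSE_TAGS = frozenset({"NOUN", "ADJ", "OTHER"})

# Penn-Treebank-style prefixes collapsed onto the coarse tagset, so
# externally tagged corpora (NN/NNS/NNP..., JJ/JJR/JJS) load unchanged.
_PENN_NOUN = ("NN",)
_PENN_ADJ = ("JJ",)


def normalize_tag(tag: str) -> str:
    """Map a raw POS tag onto the coarse tagset {NOUN, ADJ, OTHER}."""
    t = tag.strip().upper()
    if t in COARSE_TAGS:
        return t
    if t.startswith(_PENN_NOUN) or t == "NOUN":
        return "NOUN"
    if t.startswith(_PENN_ADJ) or t == "ADJ":
        return "ADJ"
    return "OTHER"


class TaggedToken(NamedTuple):
    surface: str
    pos: str

    @classmethod
    def make(cls, surface: str, pos: str) -> "TaggedToken":
        surface = surface.strip()
        if not surface:
            raise ValueError("token surface must be non-empty")
        return cls(surface, normalize_tag(pos))


@dataclass
class TaggedDocument:
    """One review: an ordered list of non-empty tagged sentences."""

    doc_id: str
    sentences: list[list[TaggedToken]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        for i, sent in enumerate(self.sentences):
            if not sent:
                raise ValueError(f"sentence {i} of {self.doc_id!r} is empty")
            self.sentences[i] = [
                t if isinstance(t, TaggedToken) else TaggedToken.make(*t)
                for t in sent
            ]

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)


# --- rule-based coarse tagger for the raw-text fallback -------------------

_STOPWORDS = frozenset(
    """a an the this that these those my your his her its our their i you he
    she it we they me him them and or but if then than so of in on at to from
    with for by about into through after before again not no never was were
    is are am be been being had have has do does did will would can could
    should may might must go went gone going get got felt feel feels said
    say says recommended recommend seemed seem very really quite too also
    there here when where while as because during""".split()
)

_ADJ_SUFFIXES = ("able", "ible", "ful", "ous", "ive", "less", "ish", "ic", "al")

_SENT_SPLIT = re.compile(r"[.!?;]+")
_TOKEN = re.compile(r"[A-Za-z][A-Za-z'-]*")


def tag_text(text: str) -> list[list[TaggedToken]]:
    """Split raw text into sentences and assign coarse POS tags.

    Heuristics: words in the default lexicon vocabulary (seeds plus
    synonym/antonym entries) are adjectives; stopwords and function words
    are OTHER; words with a typical adjectival suffix are ADJ; anything
    left is NOUN. Good enough to demo the raw-text path, and irrelevant to
    pre-tagged input.
    """
    seeds, hood = default_lexicon()
    adjectives = set(seeds.entries) | set(hood.vocabulary())
    sentences: list[list[TaggedToken]] = []
    for chunk in _SENT_SPLIT.split(text):
        words = _TOKEN.findall(chunk)
        if not words:
            continue
        tokens = []
        for w in words:
            lw = w.casefold()
            if lw in _STOPWORDS:
                pos = "OTHER"
            elif lw in adjectives or lw.endswith(_ADJ_SUFFIXES):
                pos = "ADJ"
            else:
                pos = "NOUN"
            tokens.append(TaggedToken(w, pos))
        sentences.append(tokens)
    return sentences


# --- corpus I/O -----------------------------------------------------------

def read_corpus_jsonl(path: str | Path) -> list[TaggedDocument]:
    """Read a JSON-lines corpus, tagging raw-text records internally."""
    docs: list[TaggedDocument] = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: line {lineno}: invalid JSON ({exc})") from exc
        doc_id = rec.get("doc_id")
        if not doc_id:
            raise ValueError(f"{path}: line {lineno}: missing doc_id")
        if "sentences" in rec:
            sentences = [
                [TaggedToken.make(s, p) for s, p in sent]
                for sent in rec["sentences"]
            ]
        elif "text" in rec:
            sentences = tag_text(rec["text"])
        else:
            raise ValueError(
                f"{path}: line {lineno}: record needs 'sentences' or 'text'"
            )
        docs.append(TaggedDocument(str(doc_id), sentences))
    return docs


def write_corpus_jsonl(docs: Iterable[TaggedDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            rec = {
                "doc_id": doc.doc_id,
                "sentences": [
                    [[t.surface, t.pos] for t in sent] for sent in doc.sentences
                ],
            }
            fh.write(json.dumps(rec) + "\n")
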