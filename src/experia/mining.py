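"""Aspect-level opinion mining from tagged patient reviews.

The pipeline mirrors the classic feature-based opinion-mining recipe:

1. every noun and noun phrase (maximal run of consecutive noun tokens)
   is a candidate feature, with support counted as the fraction of
   sentences in the corpus that contain it;
2. candidates at or above a minimum-support threshold are the frequent
   features;
3. in each sentence, the adjective closest (in tokens) to a frequent
   feature's span is that feature's opinion word;
4. opinion-word polarity is resolved against the seed lexicon and its
   synonym/antonym neighbourhood, sweeping repeatedly: every word a sweep
   resolves joins the seed list, and the loop stops when a full sweep
   adds nothing. Words the lexicon cannot reach are invalid words and
   yield no opinion.

The result is the set of (feature, opinion word, polarity) opinions per
sentence, plus the enlarged seed list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .lexicon import (
    LexiconNeighborhood,
    Polarity,
    SeedLexicon,
    lookup_polarity,
)
from .tagging import TaggedDocument, TaggedToken

__all__ = [
    "CandidateFeature",
    "MiningConfig",
    "Opinion",
    "OpinionSet",
    "OpinionPair",
    "extract_candidates",
    "find_frequent_features",
    "extract_opinion_words",
    "expand_seed_list",
    "propagate_polarity",
    "mine_opinions",
    "score_sentence",
    "write_opinions_tsv",
    "read_opinions_tsv",
    "write_opinions_json",
]


@dataclass(frozen=True)
class MiningConfig:
    """Mining parameters.

    threshold
        Minimum support (fraction of sentences) for a frequent feature.
    max_adjective_distance
        Maximum token distance between a feature span and its opinion
        word; ``None`` means unbounded.
    """

    threshold: float = 0.1
    max_adjective_distance: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.max_adjective_distance is not None and self.max_adjective_distance < 1:
            raise ValueError("max_adjective_distance must be >= 1 or None")


@dataclass
class CandidateFeature:
    """A noun / noun phrase with its sentence-level support."""

    phrase: str
    support: float
    sentence_ids: frozenset[tuple[str, int]]


@dataclass(frozen=True)
class Opinion:
    feature: str
    opinion_word: str
    polarity: Polarity
    doc_id: str
    sentence_index: int


@dataclass
class OpinionSet:
    """Mined opinions plus the words the lexicon could not resolve."""

    opinions: list[Opinion] = field(default_factory=list)
    invalid_words: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = {o.opinion_word for o in self.opinions} & set(self.invalid_words)
        if bad:
            raise ValueError(f"opinions carry invalid words: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.opinions)

    def __iter__(self):
        return iter(self.opinions)

    def as_tuples(self) -> set[tuple[str, str, str]]:
        return {(o.feature, o.opinion_word, o.polarity.value) for o in self.opinions}


# An opinion-word pairing before polarity resolution.
OpinionPair = tuple[str, str, str, int]  # (feature, opinion_word, doc_id, sent_idx)


def _noun_runs(sentence: Sequence[TaggedToken]) -> list[tuple[str, int, int]]:
    """Maximal runs of consecutive noun tokens as (phrase, start, end)."""
    runs = []
    i = 0
    while i < len(sentence):
        if sentence[i].pos == "NOUN":
            j = i
            while j + 1 < len(sentence) and sentence[j + 1].pos == "NOUN":
                j += 1
            phrase = " ".join(t.surface.casefold() for t in sentence[i : j + 1])
            runs.append((phrase, i, j))
            i = j + 1
        else:
            i += 1
    return runs


def extract_candidates(corpus: Sequence[TaggedDocument]) -> list[CandidateFeature]:
    """All noun phrases in the corpus with sentence-fraction support."""
    total = sum(doc.n_sentences for doc in corpus)
    if total == 0:
        raise ValueError("corpus contains no sentences")
    where: dict[str, set[tuple[str, int]]] = {}
    for doc in corpus:
        for s_idx, sent in enumerate(doc.sentences):
            for phrase, _, _ in _noun_runs(sent):
                where.setdefault(phrase, set()).add((doc.doc_id, s_idx))
    return [
        CandidateFeature(phrase, len(ids) / total, frozenset(ids))
        for phrase, ids in sorted(where.items())
    ]


def find_frequent_features(
    candidates: Sequence[CandidateFeature], config: MiningConfig
) -> list[CandidateFeature]:
    """Candidates meeting the minimum support, most supported first."""
    kept = [c for c in candidates if c.support >= config.threshold]
    return sorted(kept, key=lambda c: (-c.support, c.phrase))


def extract_opinion_words(
    corpus: Sequence[TaggedDocument],
    features: Sequence[CandidateFeature],
    config: MiningConfig,
) -> list[OpinionPair]:
    """Pair each frequent feature with its nearest in-sentence adjective.

    Distance is counted in tokens from the nearest edge of the feature
    span; an adjective before the feature wins a tie with one after it.
    Sentences containing a feature but no adjective (or none within
    ``max_adjective_distance``) contribute nothing.
    """
    frequent = {f.phrase for f in features}
    pairs: list[OpinionPair] = []
    for doc in corpus:
        for s_idx, sent in enumerate(doc.sentences):
            adj_positions = [i for i, t in enumerate(sent) if t.pos == "ADJ"]
            if not adj_positions:
                continue
            for phrase, start, end in _noun_runs(sent):
                if phrase not in frequent:
                    continue
                best: Optional[tuple[int, int, int]] = None
                for i in adj_positions:
                    dist = start - i if i < start else i - end
                    after = 0 if i < start else 1  # preceding adjective wins ties
                    key = (dist, after, i)
                    if best is None or key < best:
                        best = key
                if best is None:
                    continue
                dist, _, i = best
                if (
                    config.max_adjective_distance is not None
                    and dist > config.max_adjective_distance
                ):
                    continue
                pairs.append((phrase, sent[i].surface.casefold(), doc.doc_id, s_idx))
    return pairs


def expand_seed_list(
    words: Iterable[str],
    seeds: SeedLexicon,
    hood: LexiconNeighborhood,
) -> tuple[dict[str, Polarity], frozenset[str], SeedLexicon]:
    """Iteratively resolve word polarities, growing the seed list.

    Each sweep applies the one-hop lookup to every still-unresolved word
    and adds the words it resolves to the seed list, so later sweeps can
    reach words further from the original seeds. The loop stops when a
    sweep resolves nothing new; words left over are invalid.

    Returns ``(resolved word -> polarity, invalid words, enlarged seeds)``.
    The input seed lexicon is not modified; ``initial_size`` carries over.
    """
    if len(seeds) == 0:
        raise ValueError("seed lexicon must be non-empty")
    grown = seeds.copy()
    unresolved = sorted({w.casefold() for w in words})
    resolved: dict[str, Polarity] = {}
    changed = True
    while changed and unresolved:
        changed = False
        still = []
        for word in unresolved:
            pol = lookup_polarity(word, grown, hood)
            if pol is None:
                still.append(word)
            else:
                resolved[word] = pol
                grown.add(word, pol)
                changed = True
        unresolved = still
    return resolved, frozenset(unresolved), grown


def propagate_polarity(
    pairs: Sequence[OpinionPair],
    seeds: SeedLexicon,
    hood: LexiconNeighborhood,
) -> tuple[OpinionSet, SeedLexicon]:
    """Resolve polarities for all paired opinion words.

    Pairs whose word resolves become opinions; words the lexicon cannot
    reach are recorded as invalid and their pairs are dropped.
    """
    resolved, invalid, grown = expand_seed_list(
        (w for _, w, _, _ in pairs), seeds, hood
    )
    opinions = [
        Opinion(feat, word, resolved[word], doc_id, s_idx)
        for feat, word, doc_id, s_idx in pairs
        if word in resolved
    ]
    return OpinionSet(opinions, invalid), grown


def mine_opinions(
    corpus: Sequence[TaggedDocument],
    seeds: SeedLexicon,
    hood: LexiconNeighborhood,
    config: MiningConfig,
) -> OpinionSet:
    """Run the full mining pipeline over a tagged corpus."""
    candidates = extract_candidates(corpus)
    frequent = find_frequent_features(candidates, config)
    pairs = extract_opinion_words(corpus, frequent, config)
    opinion_set, _ = propagate_polarity(pairs, seeds, hood)
    return opinion_set


_NEGATORS = frozenset({"not", "no", "never"})
_NEGATION_WINDOW = 3


def score_sentence(
    sentence: Sequence[TaggedToken],
    seeds: SeedLexicon,
    *,
    negation: bool = False,
) -> Polarity:
    """Sentence polarity as a majority vote of seeded words.

    Counts positive- vs negative-seeded tokens; the majority wins, and a
    tie (including no seeded token at all) is neutral. With ``negation``
    enabled, a negator within three tokens before a seeded word flips
    that word's vote; off by default.
    """
    pos = neg = 0
    surfaces = [t.surface.casefold() for t in sentence]
    for i, word in enumerate(surfaces):
        polarity = seeds.polarity(word)
        if polarity is None or polarity is Polarity.NEUTRAL:
            continue
        if negation and any(
            s in _NEGATORS for s in surfaces[max(0, i - _NEGATION_WINDOW) : i]
        ):
            polarity = polarity.opposite
        if polarity is Polarity.POSITIVE:
            pos += 1
        else:
            neg += 1
    if pos > neg:
        return Polarity.POSITIVE
    if neg > pos:
        return Polarity.NEGATIVE
    return Polarity.NEUTRAL


# --- opinion table I/O ----------------------------------------------------

_TSV_COLUMNS = ["doc_id", "sentence_index", "feature", "opinion_word", "polarity"]


def write_opinions_tsv(opinions: OpinionSet, path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (o.doc_id, o.sentence_index, o.feature, o.opinion_word, o.polarity.value)
            for o in opinions
        ],
        columns=_TSV_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_opinions_tsv(path: str | Path) -> OpinionSet:
    frame = pd.read_csv(path, sep="\t", dtype={"doc_id": str})
    opinions = [
        Opinion(
            row.feature,
            row.opinion_word,
            Polarity(row.polarity),
            row.doc_id,
            int(row.sentence_index),
        )
        for row in frame.itertuples()
    ]
    return OpinionSet(opinions)


def write_opinions_json(opinions: OpinionSet, path: str | Path) -> None:
    payload = {
        "opinions": [
            {
                "doc_id": o.doc_id,
                "sentence_index": o.sentence_index,
                "feature": o.feature,
                "opinion_word": o.opinion_word,
                "polarity": o.polarity.value,
            }
            for o in opinions
        ],
        "invalid_words": sorted(opinions.invalid_words),
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
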