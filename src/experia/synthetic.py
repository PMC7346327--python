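"""Synthetic inputs with planted ground truth.

Everything the pipeline consumes can be generated here: tagged review
corpora in the style of patient social-network posts with planted
(feature, adjective, polarity) opinions, a matching seed lexicon, and
case bases whose preference vectors cluster around decision archetypes.
Each generator is a pure function of its plan and seed, and returns the
ground truth the downstream module is expected to recover.

The generated language is template English over explicit POS tags — it
emulates the *structure* real reviews feed into the miner (noun-phrase
features, nearby adjectives, filler sentences), not clinical prose.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .lexicon import LexiconNeighborhood, Polarity, SeedLexicon
from .mining import Opinion, OpinionSet
from .pekb import ExperienceCase, PreferenceAttribute
from .tagging import TaggedDocument, TaggedToken

__all__ = [
    "CorpusPlan",
    "CaseBasePlan",
    "Archetype",
    "generate_corpus",
    "lexicon_for_plan",
    "fig3_review",
    "generate_case_base",
]


@dataclass(frozen=True)
class CorpusPlan:
    """Plan for a review corpus with planted opinions.

    Each feature phrase gets the stated fraction of all sentences
    (realized counts are within one sentence of ``support * total``);
    every sentence carrying a feature also carries its planted adjective
    adjacent to it, so the mined opinion table is known in advance.
    """

    n_reviews: int
    features: tuple[tuple[str, float], ...]  # (phrase, planted support)
    adjective_map: tuple[tuple[str, str, Polarity], ...]  # (phrase, adj, polarity)
    sentences_per_review: int = 3
    threshold: Optional[float] = None  # defaults to the smallest planted support
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reviews < 1 or self.sentences_per_review < 1:
            raise ValueError("plan needs at least one review and sentence")
        phrases = [p for p, _ in self.features]
        if len(set(phrases)) != len(phrases):
            raise ValueError("feature phrases must be distinct")
        for phrase, support in self.features:
            if not 0.0 < support <= 1.0:
                raise ValueError(f"support for {phrase!r} must be in (0, 1]")
        mapped = {p for p, _, _ in self.adjective_map}
        if mapped != set(phrases):
            raise ValueError("adjective_map must cover exactly the planted features")

    @property
    def total_sentences(self) -> int:
        return self.n_reviews * self.sentences_per_review

    @property
    def effective_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        counts = [
            max(1, round(s * self.total_sentences)) for _, s in self.features
        ]
        return min(c / self.total_sentences for c in counts)


_FEATURE_TEMPLATES = (
    # (pre tokens, post tokens) around "<feature nouns> ... <adjective>"
    (("the", "OTHER"), ("was", "OTHER")),
    (("my", "OTHER"), ("felt", "OTHER")),
)

_FILLER_SENTENCES = (
    [("the", "OTHER"), ("nurse", "NOUN"), ("spoke", "OTHER"), ("with", "OTHER"),
     ("the", "OTHER"), ("doctor", "NOUN")],
    [("we", "OTHER"), ("waited", "OTHER"), ("in", "OTHER"), ("the", "OTHER"),
     ("clinic", "NOUN")],
    [("my", "OTHER"), ("family", "NOUN"), ("came", "OTHER"), ("along", "OTHER")],
)


def generate_corpus(
    plan: CorpusPlan,
) -> tuple[list[TaggedDocument], OpinionSet]:
    """Realize a plan into tagged reviews plus the expected opinion set.

    The returned opinion set is exactly what mining must output at the
    plan's threshold against a lexicon resolving the planted adjectives
    (see :func:`lexicon_for_plan`). Deterministic in the plan's seed.
    """
    rng = random.Random(plan.seed)
    total = plan.total_sentences
    counts = {
        phrase: max(1, round(support * total)) for phrase, support in plan.features
    }
    if sum(counts.values()) > total:
        raise ValueError(
            f"planted supports need {sum(counts.values())} sentences, "
            f"corpus has {total}"
        )
    adjectives = {p: (adj, pol) for p, adj, pol in plan.adjective_map}

    slots = list(range(total))
    rng.shuffle(slots)
    assignment: dict[int, str] = {}
    cursor = 0
    for phrase, _ in plan.features:
        for _ in range(counts[phrase]):
            assignment[slots[cursor]] = phrase
            cursor += 1

    docs: list[TaggedDocument] = []
    truth: list[Opinion] = []
    for r in range(plan.n_reviews):
        sentences = []
        for s in range(plan.sentences_per_review):
            slot = r * plan.sentences_per_review + s
            phrase = assignment.get(slot)
            if phrase is None:
                sentences.append(
                    [TaggedToken(*t) for t in rng.choice(_FILLER_SENTENCES)]
                )
                continue
            adj, polarity = adjectives[phrase]
            pre, post = rng.choice(_FEATURE_TEMPLATES)
            tokens = [TaggedToken(*pre)]
            tokens += [TaggedToken(w, "NOUN") for w in phrase.split()]
            tokens += [TaggedToken(*post), TaggedToken(adj, "ADJ")]
            sentences.append(tokens)
            truth.append(
                Opinion(
                    feature=phrase,
                    opinion_word=adj,
                    polarity=polarity,
                    doc_id=f"review-{r:04d}",
                    sentence_index=s,
                )
            )
        docs.append(TaggedDocument(f"review-{r:04d}", sentences))
    # features below the effective threshold plant no opinions
    thr = plan.effective_threshold
    truth = [
        o
        for o in truth
        if counts[o.feature] / total >= thr
    ]
    return docs, OpinionSet(truth)


def lexicon_for_plan(plan: CorpusPlan) -> tuple[SeedLexicon, LexiconNeighborhood]:
    """A seed lexicon that resolves exactly the plan's adjectives.

    Three anchor seeds carry the polarities; each planted adjective is
    linked to its anchor as a synonym, so resolving it exercises the
    propagation loop rather than a direct seed hit.
    """
    anchors = {
        Polarity.POSITIVE: "good",
        Polarity.NEGATIVE: "bad",
        Polarity.NEUTRAL: "plain",
    }
    seeds = SeedLexicon(
        {word: pol for pol, word in anchors.items()}
    )
    synonyms: dict[str, set[str]] = {}
    for _, adj, pol in plan.adjective_map:
        if adj in seeds:
            continue
        synonyms.setdefault(adj, set()).add(anchors[pol])
    return seeds, LexiconNeighborhood(synonyms, {})


def fig3_review() -> tuple[TaggedDocument, OpinionSet, float]:
    """The worked patient-review example, hand-tagged.

    A five-sentence breast-cancer review whose frequent noun phrases are
    "stereotactic biopsy", "left breast", "mastectomy" (and "pain"), with
    opinion words "excruciating", "unbearable" and "radical", all of
    which the default lexicon resolves to negative. Returns the document,
    the expected opinion set at the returned support threshold (0.4) and
    that threshold. Deterministic: the fixture has no randomness.
    """
    O, N, A = "OTHER", "NOUN", "ADJ"
    sentences = [
        [("i", O), ("had", O), ("a", O), ("stereotactic", N), ("biopsy", N),
         ("on", O), ("my", O), ("left", N), ("breast", N)],
        [("the", O), ("pain", N), ("from", O), ("the", O), ("stereotactic", N),
         ("biopsy", N), ("was", O), ("excruciating", A)],
        [("the", O), ("pain", N), ("in", O), ("my", O), ("left", N),
         ("breast", N), ("was", O), ("unbearable", A)],
        [("my", O), ("doctor", N), ("recommended", O), ("a", O),
         ("radical", A), ("mastectomy", N)],
        [("after", O), ("the", O), ("mastectomy", N), ("i", O), ("will", O),
         ("not", O), ("go", O), ("through", O), ("that", O), ("torture", N),
         ("again", O)],
    ]
    doc = TaggedDocument(
        "plm-fig3", [[TaggedToken(w, p) for w, p in s] for s in sentences]
    )
    neg = Polarity.NEGATIVE
    expected = OpinionSet(
        [
            Opinion("pain", "excruciating", neg, "plm-fig3", 1),
            Opinion("stereotactic biopsy", "excruciating", neg, "plm-fig3", 1),
            Opinion("left breast", "unbearable", neg, "plm-fig3", 2),
            Opinion("pain", "unbearable", neg, "plm-fig3", 2),
            Opinion("mastectomy", "radical", neg, "plm-fig3", 3),
        ]
    )
    return doc, expected, 0.4


@dataclass(frozen=True)
class Archetype:
    """A preference/decision cluster centre for case generation."""

    centroid: tuple[float, ...]
    conditions: frozenset[str]
    decision: str
    dispersion: float = 5.0
    outcome: Polarity = Polarity.POSITIVE


@dataclass(frozen=True)
class CaseBasePlan:
    """Plan for a case base clustered around decision archetypes."""

    n_cases: int
    attribute_names: tuple[str, ...]
    archetypes: tuple[Archetype, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or not self.archetypes:
            raise ValueError("plan needs cases and at least one archetype")
        for arch in self.archetypes:
            if len(arch.centroid) != len(self.attribute_names):
                raise ValueError("centroid length must match attribute schema")
            if arch.dispersion < 0:
                raise ValueError("dispersion must be non-negative")
            if not arch.conditions:
                raise ValueError("archetype conditions must be non-empty")


def generate_case_base(
    plan: CaseBasePlan,
) -> tuple[list[ExperienceCase], list[int]]:
    """Draw cases around the plan's archetypes.

    Each case picks an archetype uniformly at random, then draws its VAS
    vector from a Gaussian at the centroid (standard deviation =
    dispersion, clipped to [0, 100]) and inherits the archetype's
    conditions and decision. Returns the cases and their ground-truth
    archetype indices; deterministic in the plan's seed.
    """
    rng = random.Random(plan.seed)
    n_attr = len(plan.attribute_names)
    cases: list[ExperienceCase] = []
    labels: list[int] = []
    for i in range(plan.n_cases):
        a_idx = rng.randrange(len(plan.archetypes))
        arch = plan.archetypes[a_idx]
        values = [
            min(100.0, max(0.0, rng.gauss(mu, arch.dispersion)))
            for mu in arch.centroid
        ]
        vector = tuple(
            PreferenceAttribute(name, value, rank)
            for rank, (name, value) in enumerate(
                zip(plan.attribute_names, values), start=1
            )
        )
        cases.append(
            ExperienceCase(
                case_id=f"case-{i:04d}",
                conditions=arch.conditions,
                preference_vector=vector,
                decision=arch.decision,
                overall_polarity=arch.outcome,
            )
        )
        labels.append(a_idx)
    return cases, labels
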