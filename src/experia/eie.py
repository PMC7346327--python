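"""Experience inference engine: KNN retrieval over stored cases.

A query patient carries a set of clinical conditions and a preference
vector of VAS values (one per preference attribute, each with a priority
rank). Retrieval is two-staged, conditions first: cases whose condition
set matches the query are kept, then ranked by Euclidean distance
between preference vectors on the normalized [0, 1] scale. The k nearest
cases receive normalized inverse-distance weights ("probability of
similarity"), and those weights are accumulated per stored decision to
re-rank an externally supplied, already-ordered list of objective
candidate decisions.

Priority ranks can optionally weight the distance (higher-priority
attributes count more); this is off by default so the plain Euclidean
distance is what retrieval uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

from .pekb import (
    ExperienceCase,
    PekbStore,
    PreferenceAttribute,
    match_conditions,
    normalize_condition,
)

__all__ = [
    "QueryPatient",
    "InferenceConfig",
    "SimilarityResult",
    "RetrievalOutcome",
    "RankedDecision",
    "local_similarity",
    "global_distance",
    "knn_retrieve",
    "compute_weights",
    "rerank_decisions",
    "what_if",
]

_VAS_SCALE = 100.0


@dataclass(frozen=True)
class QueryPatient:
    """The patient being advised: conditions plus preference vector."""

    conditions: frozenset[str]
    preference_vector: tuple[PreferenceAttribute, ...]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("query conditions must be non-empty")
        object.__setattr__(
            self,
            "conditions",
            frozenset(normalize_condition(c) for c in self.conditions),
        )
        object.__setattr__(
            self,
            "preference_vector",
            tuple(PreferenceAttribute(*p) for p in self.preference_vector),
        )
        for attr in self.preference_vector:
            if not 0.0 <= attr.value <= 100.0:
                raise ValueError(
                    f"VAS value {attr.value} for {attr.name!r} outside [0, 100]"
                )
        ranks = sorted(a.rank for a in self.preference_vector)
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"priority ranks {ranks} are not a permutation of 1..n")

    def preference_values(self) -> dict[str, float]:
        return {a.name: a.value for a in self.preference_vector}

    def with_attribute(self, name: str, value: float) -> "QueryPatient":
        """A copy with one preference attribute's VAS value replaced."""
        names = [a.name for a in self.preference_vector]
        if name not in names:
            raise KeyError(f"unknown preference attribute {name!r}")
        new_vector = tuple(
            PreferenceAttribute(a.name, value if a.name == name else a.value, a.rank)
            for a in self.preference_vector
        )
        return replace(self, preference_vector=new_vector)


@dataclass(frozen=True)
class InferenceConfig:
    """Retrieval parameters.

    k is the number of nearest cases kept (a hyper-parameter, set by
    experience; default 5). Condition matching is a hard pre-filter with
    three rules (exact / subset / jaccard >= theta). epsilon guards the
    inverse-distance weight against division by zero on exact matches.
    """

    k: int = 5
    condition_match_rule: str = "subset"
    jaccard_theta: float = 0.5
    weight_scheme: str = "inverse_distance"
    use_priority_weights: bool = False
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.condition_match_rule not in ("exact", "subset", "jaccard"):
            raise ValueError(f"unknown rule {self.condition_match_rule!r}")
        if self.weight_scheme not in ("inverse_distance", "rank"):
            raise ValueError(f"unknown weight scheme {self.weight_scheme!r}")


@dataclass
class SimilarityResult:
    """One retrieved case with its per-attribute and global similarity."""

    case_id: str
    local_similarities: dict[str, float]
    distance: float
    weight: float = 0.0


@dataclass
class RetrievalOutcome:
    """KNN retrieval output; ``status`` flags the no-evidence situation."""

    results: list[SimilarityResult] = field(default_factory=list)
    status: str = "ok"  # "ok" | "no_experience"

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)


@dataclass
class RankedDecision:
    decision: str
    experience_weight: float
    original_rank: int
    final_rank: int


def local_similarity(a_query: float, a_case: float) -> float:
    """Per-attribute similarity: 1 - |difference| / scale, in [0, 1]."""
    for v in (a_query, a_case):
        if not 0.0 <= v <= _VAS_SCALE:
            raise ValueError(f"VAS value {v} outside [0, {_VAS_SCALE:.0f}]")
    return 1.0 - abs(a_query - a_case) / _VAS_SCALE


def _priority_weights(vector: Sequence[PreferenceAttribute]) -> dict[str, float]:
    # weight_i = (n - rank_i + 1) / sum(ranks); sums to 1 over a permutation
    n = len(vector)
    total = sum(a.rank for a in vector)
    return {a.name: (n - a.rank + 1) / total for a in vector}


def global_distance(
    q: QueryPatient, c: ExperienceCase, *, use_priority_weights: bool = False
) -> float:
    """Euclidean distance between preference vectors on the [0, 1] scale.

    Requires the query and the case to share the same attribute schema
    (same attribute names); attributes are aligned by name. With priority
    weighting enabled, each squared difference is scaled by the query's
    normalized priority weight.
    """
    qv = q.preference_values()
    cv = c.preference_values()
    if set(qv) != set(cv):
        raise ValueError(
            f"attribute schemas differ: {sorted(qv)} vs {sorted(cv)}"
        )
    weights = (
        _priority_weights(q.preference_vector)
        if use_priority_weights
        else {name: 1.0 for name in qv}
    )
    return math.sqrt(
        sum(
            weights[name] * ((qv[name] - cv[name]) / _VAS_SCALE) ** 2
            for name in qv
        )
    )


def knn_retrieve(
    q: QueryPatient,
    store: PekbStore | Sequence[ExperienceCase],
    cfg: InferenceConfig = InferenceConfig(),
) -> RetrievalOutcome:
    """Select the k nearest condition-matched cases.

    Conditions filter first; survivors are sorted by global distance with
    deterministic ties broken by case id. When no stored case matches the
    query's conditions the outcome carries the ``no_experience`` status
    instead of raising.
    """
    if isinstance(store, PekbStore):
        matched = store.query_by_condition(
            q.conditions, rule=cfg.condition_match_rule, theta=cfg.jaccard_theta
        )
    else:
        matched = [
            c
            for c in store
            if match_conditions(
                q.conditions,
                c.conditions,
                rule=cfg.condition_match_rule,
                theta=cfg.jaccard_theta,
            )
        ]
    if not matched:
        return RetrievalOutcome(results=[], status="no_experience")
    scored = sorted(
        (
            (
                global_distance(
                    q, c, use_priority_weights=cfg.use_priority_weights
                ),
                c.case_id,
                c,
            )
            for c in matched
        ),
        key=lambda t: (t[0], t[1]),
    )
    qv = q.preference_values()
    results = [
        SimilarityResult(
            case_id=cid,
            local_similarities={
                name: local_similarity(qv[name], c.preference_values()[name])
                for name in qv
            },
            distance=dist,
        )
        for dist, cid, c in scored[: cfg.k]
    ]
    return RetrievalOutcome(results=compute_weights(results, cfg), status="ok")


def compute_weights(
    results: list[SimilarityResult], cfg: InferenceConfig = InferenceConfig()
) -> list[SimilarityResult]:
    """Normalized case weights, summing to one.

    ``inverse_distance`` (default): w_i proportional to 1/(d_i + epsilon),
    strictly decreasing in distance. ``rank``: linearly decaying with the
    position in the distance ordering.
    """
    if not results:
        raise ValueError("cannot weight an empty result list")
    if cfg.weight_scheme == "inverse_distance":
        raw = [1.0 / (r.distance + cfg.epsilon) for r in results]
    else:
        n = len(results)
        raw = [float(n - i) for i in range(n)]
    total = sum(raw)
    for r, w in zip(results, raw):
        r.weight = w / total
    return results


def rerank_decisions(
    objective: Sequence[str],
    results: Sequence[SimilarityResult],
    case_lookup: Callable[[str], ExperienceCase],
) -> list[RankedDecision]:
    """Re-rank objective candidate decisions by accumulated case weights.

    Each candidate's experience weight is the sum of the weights of
    retrieved cases whose stored decision equals it. Candidates sort by
    weight descending, ties (including the all-zero no-evidence case) by
    their original objective order; the output is a permutation of the
    input.
    """
    if not objective:
        raise ValueError("objective candidate list must be non-empty")
    norm = [normalize_condition(d) for d in objective]
    accumulated = dict.fromkeys(norm, 0.0)
    for res in results:
        case = case_lookup(res.case_id)
        if case.decision is None:
            continue
        decision = normalize_condition(case.decision)
        if decision in accumulated:
            accumulated[decision] += res.weight
    order = sorted(
        range(len(objective)), key=lambda i: (-accumulated[norm[i]], i)
    )
    return [
        RankedDecision(
            decision=objective[i],
            experience_weight=accumulated[norm[i]],
            original_rank=i + 1,
            final_rank=pos + 1,
        )
        for pos, i in enumerate(order)
    ]


def recommend(
    q: QueryPatient,
    store: PekbStore | Sequence[ExperienceCase],
    objective: Sequence[str],
    cfg: InferenceConfig = InferenceConfig(),
) -> tuple[RetrievalOutcome, list[RankedDecision]]:
    """Full inference: retrieve k nearest cases, then re-rank candidates."""
    outcome = knn_retrieve(q, store, cfg)
    if isinstance(store, PekbStore):
        lookup = store.get_case
    else:
        by_id = {c.case_id: c for c in store}
        lookup = by_id.__getitem__
    ranked = rerank_decisions(objective, outcome.results, lookup)
    return outcome, ranked


def what_if(
    q: QueryPatient,
    attribute: str,
    new_value: float,
    store: PekbStore | Sequence[ExperienceCase],
    cfg: InferenceConfig = InferenceConfig(),
    objective: Optional[Sequence[str]] = None,
) -> tuple[RetrievalOutcome, Optional[list[RankedDecision]]]:
    """Recompute retrieval with one preference attribute substituted.

    Pure: the original query object is unchanged. Raises KeyError for an
    attribute outside the schema. When an objective candidate list is
    given the re-ranking is recomputed as well.
    """
    modified = q.with_attribute(attribute, new_value)
    outcome = knn_retrieve(modified, store, cfg)
    if objective is None:
        return outcome, None
    if isinstance(store, PekbStore):
        lookup = store.get_case
    else:
        by_id = {c.case_id: c for c in store}
        lookup = by_id.__getitem__
    return outcome, rerank_decisions(objective, outcome.results, lookup)
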