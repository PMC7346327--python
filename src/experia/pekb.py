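"""Patient Experience Knowledge Base: ontology individuals in RDF.

Mined opinions plus patient metadata are mapped onto a small clinical
sentiment ontology (clinical concepts + opinion-annotation concepts + an
application layer, one merged schema with three prefixes) and stored as
RDF triples. Turtle is the canonical persistence format; a JSON mirror of
the case store exists for the inference engine's hot path, with a
bijection between the two verified in the test suite.

Every emitted triple's predicate must be declared in the shipped schema;
individuals are named by stable URIs (no blank nodes), so a saved store
reloads to the identical triple set.
"""

from __future__ import annotations

import json
import re
from decimal import Decimal
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

from rdflib import RDF, RDFS, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL

from .lexicon import Polarity
from .mining import Opinion, OpinionSet

__all__ = [
    "CSO",
    "MARL",
    "OGMS",
    "PEKB_BASE",
    "SchemaError",
    "ConflictError",
    "PreferenceAttribute",
    "ExperienceCase",
    "normalize_condition",
    "load_schema",
    "schema_classes",
    "schema_properties",
    "case_to_graph",
    "map_opinions_to_individuals",
    "PekbStore",
    "match_conditions",
]

CSO = Namespace("http://example.org/experia/cso#")
MARL = Namespace("http://www.gsi.upm.es/ontologies/marl/ns#")
OGMS = Namespace("http://example.org/experia/ogms#")
PEKB_BASE = "http://example.org/experia/pekb/"


class SchemaError(ValueError):
    """A triple uses a class or property the schema does not declare."""


class ConflictError(ValueError):
    """A case with the same identifier is already stored."""


def load_schema() -> Graph:
    """The shipped ontology schema as an rdflib graph."""
    text = resources.files("experia").joinpath("data/cso_schema.ttl").read_text()
    g = Graph()
    g.parse(data=text, format="turtle")
    return g


def schema_classes(schema: Optional[Graph] = None) -> frozenset[URIRef]:
    g = schema if schema is not None else load_schema()
    return frozenset(g.subjects(RDF.type, OWL.Class))


def schema_properties(schema: Optional[Graph] = None) -> frozenset[URIRef]:
    g = schema if schema is not None else load_schema()
    declared = set(g.subjects(RDF.type, RDF.Property))
    # rdf:type and rdfs:label are structural vocabulary, always permitted.
    declared |= {RDF.type, RDFS.label}
    return frozenset(declared)


def normalize_condition(term: str) -> str:
    """Free-text condition normalization: case-fold, collapse whitespace."""
    return " ".join(term.casefold().split())


class PreferenceAttribute(NamedTuple):
    """One elicited preference: a named VAS value with a priority rank."""

    name: str
    value: float
    rank: int


@dataclass(frozen=True)
class ExperienceCase:
    """One stored patient-experience record.

    Conditions are normalized free-text terms; the preference vector
    holds VAS values in [0, 100] whose priority ranks form a permutation
    of 1..n.
    """

    case_id: str
    conditions: frozenset[str]
    procedure: Optional[str] = None
    opinions: tuple[Opinion, ...] = ()
    preference_vector: tuple[PreferenceAttribute, ...] = ()
    decision: Optional[str] = None
    overall_polarity: Polarity = Polarity.NEUTRAL

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        object.__setattr__(
            self, "conditions", frozenset(normalize_condition(c) for c in self.conditions)
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

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.preference_vector)

    def preference_values(self) -> dict[str, float]:
        return {a.name: a.value for a in self.preference_vector}


# --- case <-> triples ------------------------------------------------------

_SLUG = re.compile(r"[^a-z0-9]+")


def _slug(text: str) -> str:
    return _SLUG.sub("-", text.casefold()).strip("-") or "x"


def _case_uri(case_id: str) -> URIRef:
    return URIRef(PEKB_BASE + "case/" + _slug(case_id))


class _Emitter:
    """Adds triples to a graph, refusing undeclared predicates/classes."""

    def __init__(self, graph: Graph, schema: Graph):
        self.graph = graph
        self.properties = schema_properties(schema)
        self.classes = schema_classes(schema)

    def add(self, s, p, o) -> None:
        if p not in self.properties:
            raise SchemaError(f"predicate {p} is not declared in the schema")
        if p == RDF.type and o not in self.classes:
            raise SchemaError(f"class {o} is not declared in the schema")
        self.graph.add((s, p, o))


def _bind_prefixes(graph: Graph) -> Graph:
    graph.bind("cso", CSO)
    graph.bind("marl", MARL)
    graph.bind("ogms", OGMS)
    return graph


def case_to_graph(case: ExperienceCase, schema: Optional[Graph] = None) -> Graph:
    """Emit one case as ontology individuals.

    The case node links its condition set, its opinion set (one opinion
    individual per mined opinion, sharing one described-object node per
    feature), its procedure/decision literals and its VAS preference
    attributes. All nodes are URI-named so the triple set round-trips.
    """
    g = _bind_prefixes(Graph())
    emit = _Emitter(g, schema if schema is not None else load_schema())
    case_uri = _case_uri(case.case_id)
    emit.add(case_uri, RDF.type, CSO.AnalyzedExperience)
    emit.add(case_uri, CSO.hasCaseId, Literal(case.case_id))
    emit.add(case_uri, MARL.hasPolarity, Literal(case.overall_polarity.value))

    condset = URIRef(str(case_uri) + "/conditions")
    emit.add(case_uri, CSO.hasConditions, condset)
    emit.add(condset, RDF.type, CSO.ClinicalConditionSet)
    for cond in sorted(case.conditions):
        emit.add(condset, CSO.hasCondition, Literal(cond))

    if case.procedure is not None:
        emit.add(case_uri, CSO.hasProcedure, Literal(case.procedure))
    if case.decision is not None:
        emit.add(case_uri, CSO.hasDecision, Literal(case.decision))

    if case.opinions:
        opset = URIRef(str(case_uri) + "/opinions")
        emit.add(case_uri, CSO.hasOpinionSet, opset)
        emit.add(opset, RDF.type, CSO.ClinicalOpinionSet)
        for i, op in enumerate(case.opinions):
            node = URIRef(str(case_uri) + f"/opinion/{i}")
            emit.add(opset, MARL.hasOpinion, node)
            emit.add(node, RDF.type, MARL.Opinion)
            obj = URIRef(str(case_uri) + "/object/" + _slug(op.feature))
            emit.add(node, MARL.describesObject, obj)
            emit.add(obj, RDF.type, MARL.DescribedObject)
            emit.add(obj, RDFS.label, Literal(op.feature))
            emit.add(node, CSO.hasOpinionWord, Literal(op.opinion_word))
            emit.add(node, MARL.hasPolarity, Literal(op.polarity.value))
            emit.add(node, CSO.fromDocument, Literal(op.doc_id))
            emit.add(node, CSO.atSentenceIndex, Literal(op.sentence_index))

    for j, attr in enumerate(case.preference_vector):
        node = URIRef(str(case_uri) + f"/pref/{j}")
        emit.add(case_uri, CSO.hasPreferenceAttribute, node)
        emit.add(node, RDF.type, CSO.AnalyzedExperienceAspect)
        emit.add(node, CSO.hasAttributeName, Literal(attr.name))
        # xsd:decimal with repr lexical form: survives Turtle round-trips
        # bit-exactly, unlike xsd:double whose lexical form is rewritten
        emit.add(node, CSO.hasVasValue, Literal(Decimal(repr(float(attr.value)))))
        emit.add(node, CSO.hasPriorityRank, Literal(int(attr.rank)))
    return g


def map_opinions_to_individuals(opinions: OpinionSet | Sequence[Opinion], meta: dict) -> Graph:
    """Map mined opinions plus patient metadata to ontology individuals.

    ``meta`` supplies the case skeleton: ``case_id``, ``conditions`` and
    optionally ``procedure``, ``decision``, ``preference_vector`` and
    ``overall_polarity``. An empty opinion set yields just the skeleton.
    """
    case = ExperienceCase(
        case_id=str(meta["case_id"]),
        conditions=frozenset(meta["conditions"]),
        procedure=meta.get("procedure"),
        opinions=tuple(opinions),
        preference_vector=tuple(
            PreferenceAttribute(p[0], float(p[1]), int(p[2]))
            for p in meta.get("preference_vector", ())
        ),
        decision=meta.get("decision"),
        overall_polarity=Polarity(meta.get("overall_polarity", "neutral")),
    )
    return case_to_graph(case)


def _graph_to_case(g: Graph, case_uri: URIRef) -> ExperienceCase:
    def one(pred, subject=case_uri):
        values = list(g.objects(subject, pred))
        return values[0] if values else None

    case_id = str(one(CSO.hasCaseId))
    condset = one(CSO.hasConditions)
    conditions = frozenset(str(c) for c in g.objects(condset, CSO.hasCondition))
    procedure = one(CSO.hasProcedure)
    decision = one(CSO.hasDecision)
    polarity = Polarity(str(one(MARL.hasPolarity)))

    opinions: list[tuple[int, Opinion]] = []
    opset = one(CSO.hasOpinionSet)
    if opset is not None:
        for node in g.objects(opset, MARL.hasOpinion):
            idx = int(str(node).rsplit("/", 1)[-1])
            obj = next(g.objects(node, MARL.describesObject))
            feature = str(next(g.objects(obj, RDFS.label)))
            opinions.append(
                (
                    idx,
                    Opinion(
                        feature=feature,
                        opinion_word=str(next(g.objects(node, CSO.hasOpinionWord))),
                        polarity=Polarity(str(next(g.objects(node, MARL.hasPolarity)))),
                        doc_id=str(next(g.objects(node, CSO.fromDocument))),
                        sentence_index=int(next(g.objects(node, CSO.atSentenceIndex))),
                    ),
                )
            )
    prefs: list[tuple[int, PreferenceAttribute]] = []
    for node in g.objects(case_uri, CSO.hasPreferenceAttribute):
        idx = int(str(node).rsplit("/", 1)[-1])
        prefs.append(
            (
                idx,
                PreferenceAttribute(
                    name=str(next(g.objects(node, CSO.hasAttributeName))),
                    value=float(next(g.objects(node, CSO.hasVasValue))),
                    rank=int(next(g.objects(node, CSO.hasPriorityRank))),
                ),
            )
        )
    return ExperienceCase(
        case_id=case_id,
        conditions=conditions,
        procedure=str(procedure) if procedure is not None else None,
        opinions=tuple(op for _, op in sorted(opinions, key=lambda t: t[0])),
        preference_vector=tuple(p for _, p in sorted(prefs, key=lambda t: t[0])),
        decision=str(decision) if decision is not None else None,
        overall_polarity=polarity,
    )


def match_conditions(
    query: frozenset[str] | set[str],
    case: frozenset[str] | set[str],
    rule: str = "subset",
    theta: float = 0.5,
) -> bool:
    """Condition-matching rules for case retrieval.

    ``exact``: the sets are equal. ``subset`` (default): every query
    condition appears in the case. ``jaccard``: Jaccard overlap >= theta.
    """
    q = {normalize_condition(c) for c in query}
    c = {normalize_condition(x) for x in case}
    if rule == "exact":
        return q == c
    if rule == "subset":
        return q <= c
    if rule == "jaccard":
        union = q | c
        if not union:
            return True
        return len(q & c) / len(union) >= theta
    raise ValueError(f"unknown condition match rule {rule!r}")


class PekbStore:
    """A triple store of experience cases with query and persistence."""

    def __init__(self, graph: Optional[Graph] = None):
        self.schema = load_schema()
        self.graph = _bind_prefixes(graph if graph is not None else Graph())

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self.graph.serialize(destination=str(path), format="turtle")

    @classmethod
    def load(cls, path: str | Path) -> "PekbStore":
        g = Graph()
        try:
            g.parse(str(path), format="turtle")
        except Exception as exc:  # rdflib reports line/column in its message
            raise ValueError(f"cannot parse {path} as Turtle: {exc}") from exc
        return cls(graph=g)

    # -- case access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.case_ids())

    def triples(self) -> set:
        return set(self.graph)

    def case_ids(self) -> list[str]:
        return sorted(
            str(o) for o in self.graph.objects(None, CSO.hasCaseId)
        )

    def _uri_for(self, case_id: str) -> Optional[URIRef]:
        for s in self.graph.subjects(CSO.hasCaseId, Literal(case_id)):
            return s
        return None

    def get_case(self, case_id: str) -> ExperienceCase:
        uri = self._uri_for(case_id)
        if uri is None:
            raise KeyError(case_id)
        return _graph_to_case(self.graph, uri)

    def cases(self) -> list[ExperienceCase]:
        return [self.get_case(cid) for cid in self.case_ids()]

    def add_case(self, case: ExperienceCase) -> None:
        """Register a learned case; duplicate identifiers are rejected."""
        if self._uri_for(case.case_id) is not None:
            raise ConflictError(f"case {case.case_id!r} already stored")
        for triple in case_to_graph(case, self.schema):
            self.graph.add(triple)

    def query_by_condition(
        self,
        conditions: Iterable[str],
        rule: str = "subset",
        theta: float = 0.5,
    ) -> list[ExperienceCase]:
        """Cases whose condition set matches the query under the rule."""
        query = frozenset(conditions)
        return [
            case
            for case in self.cases()
            if match_conditions(query, case.conditions, rule=rule, theta=theta)
        ]

    # -- JSON mirror -------------------------------------------------------

    def to_json(self) -> dict:
        return {"cases": [case_to_json(c) for c in self.cases()]}

    @classmethod
    def from_json(cls, payload: dict) -> "PekbStore":
        store = cls()
        for rec in payload["cases"]:
            store.add_case(case_from_json(rec))
        return store

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2), encoding="utf-8")

    @classmethod
    def load_json(cls, path: str | Path) -> "PekbStore":
        return cls.from_json(json.loads(Path(path).read_text(encoding="utf-8")))


def case_to_json(case: ExperienceCase) -> dict:
    return {
        "case_id": case.case_id,
        "conditions": sorted(case.conditions),
        "procedure": case.procedure,
        "opinions": [
            {
                "feature": o.feature,
                "opinion_word": o.opinion_word,
                "polarity": o.polarity.value,
                "doc_id": o.doc_id,
                "sentence_index": o.sentence_index,
            }
            for o in case.opinions
        ],
        "preference_vector": [
            {"name": a.name, "value": a.value, "rank": a.rank}
            for a in case.preference_vector
        ],
        "decision": case.decision,
        "overall_polarity": case.overall_polarity.value,
    }


def case_from_json(rec: dict) -> ExperienceCase:
    return ExperienceCase(
        case_id=rec["case_id"],
        conditions=frozenset(rec["conditions"]),
        procedure=rec.get("procedure"),
        opinions=tuple(
            Opinion(
                feature=o["feature"],
                opinion_word=o["opinion_word"],
                polarity=Polarity(o["polarity"]),
                doc_id=o["doc_id"],
                sentence_index=int(o["sentence_index"]),
            )
            for o in rec.get("opinions", ())
        ),
        preference_vector=tuple(
            PreferenceAttribute(p["name"], float(p["value"]), int(p["rank"]))
            for p in rec.get("preference_vector", ())
        ),
        decision=rec.get("decision"),
        overall_polarity=Polarity(rec.get("overall_polarity", "neutral")),
    )
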