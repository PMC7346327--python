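import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from experia.eie import (
    InferenceConfig,
    QueryPatient,
    SimilarityResult,
    compute_weights,
    global_distance,
    knn_retrieve,
    local_similarity,
    recommend,
    rerank_decisions,
    what_if,
)
from experia.pekb import ExperienceCase, PreferenceAttribute
from experia.synthetic import Archetype, CaseBasePlan, generate_case_base

from oracles import exhaustive_knn

ATTRS = ("pain_tolerance", "recovery_time", "cost")


def make_case(case_id, values, decision="mastectomy",
              conditions=("breast cancer",)):
    return ExperienceCase(
        case_id=case_id,
        conditions=frozenset(conditions),
        preference_vector=tuple(
            PreferenceAttribute(a, v, r)
            for r, (a, v) in enumerate(zip(ATTRS, values), start=1)
        ),
        decision=decision,
    )


def make_query(values, conditions=("breast cancer",)):
    return QueryPatient(
        conditions=frozenset(conditions),
        preference_vector=tuple(
            PreferenceAttribute(a, v, r)
            for r, (a, v) in enumerate(zip(ATTRS, values), start=1)
        ),
    )


def random_cases(rng, n, conditions=("breast cancer",)):
    return [
        make_case(
            f"case-{i:04d}",
            [rng.uniform(0, 100) for _ in ATTRS],
            decision=rng.choice(["mastectomy", "lumpectomy", "surveillance"]),
            conditions=conditions,
        )
        for i in range(n)
    ]


class TestLocalSimilarity:
    @pytest.mark.parametrize(
        "a,b,expected", [(50, 50, 1.0), (0, 100, 0.0), (30, 70, 0.6)]
    )
    def test_values(self, a, b, expected):
        assert local_similarity(a, b) == pytest.approx(expected)

    def test_symmetric(self):
        assert local_similarity(12, 87) == local_similarity(87, 12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            local_similarity(101, 50)


class TestGlobalDistance:
    def test_identical_vectors_at_zero(self):
        q = make_query([10, 20, 30])
        c = make_case("c", [10, 20, 30])
        assert global_distance(q, c) == 0.0

    def test_unit_distance_for_full_scale_difference(self):
        q = QueryPatient(
            frozenset({"x"}),
            (PreferenceAttribute("a", 0, 1), PreferenceAttribute("b", 50, 2)),
        )
        c = ExperienceCase(
            "c", frozenset({"x"}),
            preference_vector=(
                PreferenceAttribute("a", 100, 1),
                PreferenceAttribute("b", 50, 2),
            ),
        )
        assert global_distance(q, c) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=40)
    @given(
        qv=st.lists(st.floats(0, 100), min_size=5, max_size=5),
        cv=st.lists(st.floats(0, 100), min_size=5, max_size=5),
    )
    def test_matches_brute_force(self, qv, cv):
        names = [f"a{i}" for i in range(5)]
        q = QueryPatient(
            frozenset({"x"}),
            tuple(PreferenceAttribute(n, v, r)
                  for r, (n, v) in enumerate(zip(names, qv), 1)),
        )
        c = ExperienceCase(
            "c", frozenset({"x"}),
            preference_vector=tuple(
                PreferenceAttribute(n, v, r)
                for r, (n, v) in enumerate(zip(names, cv), 1)
            ),
        )
        expected = math.sqrt(sum(((a - b) / 100) ** 2 for a, b in zip(qv, cv)))
        assert global_distance(q, c) == pytest.approx(expected)

    def test_mismatched_schema_rejected(self):
        q = make_query([10, 20, 30])
        c = ExperienceCase(
            "c", frozenset({"x"}),
            preference_vector=(PreferenceAttribute("other", 5, 1),),
        )
        with pytest.raises(ValueError, match="schemas differ"):
            global_distance(q, c)


class TestKnnRetrieve:
    def test_single_matching_case_gets_full_weight(self):
        cases = [make_case("only", [50, 50, 50])]
        out = knn_retrieve(make_query([10, 10, 10]), cases, InferenceConfig(k=3))
        assert out.status == "ok"
        assert [r.weight for r in out.results] == [1.0]

    def test_planted_nearest_case_comes_first(self):
        rng = random.Random(5)
        cases = random_cases(rng, 50)
        query_values = [33.0, 66.0, 12.0]
        cases.append(make_case("planted", query_values))
        out = knn_retrieve(make_query(query_values), cases, InferenceConfig(k=5))
        assert out.results[0].case_id == "planted"
        assert out.results[0].distance == 0.0

    def test_no_condition_match_returns_status_flag(self):
        cases = random_cases(random.Random(6), 10)
        out = knn_retrieve(
            make_query([50, 50, 50], conditions=("unrelated condition",)), cases
        )
        assert out.status == "no_experience"
        assert out.results == []

    def test_agrees_with_exhaustive_sort(self):
        rng = random.Random(7)
        for _ in range(10):
            n = rng.randint(1, 80)
            cases = random_cases(rng, n)
            qv = [rng.uniform(0, 100) for _ in ATTRS]
            k = rng.randint(1, 10)
            out = knn_retrieve(make_query(qv), cases, InferenceConfig(k=k))
            oracle = exhaustive_knn(
                dict(zip(ATTRS, qv)),
                {c.case_id: c.preference_values() for c in cases},
                k,
            )
            assert [r.case_id for r in out.results] == [cid for cid, _ in oracle]
            for r, (_, d) in zip(out.results, oracle):
                assert r.distance == pytest.approx(d)

    def test_retrieved_distances_bound_excluded_ones(self):
        rng = random.Random(8)
        cases = random_cases(rng, 30)
        q = make_query([40, 60, 20])
        out = knn_retrieve(q, cases, InferenceConfig(k=5))
        kept = {r.case_id for r in out.results}
        worst_kept = max(r.distance for r in out.results)
        for c in cases:
            if c.case_id not in kept:
                assert global_distance(q, c) >= worst_kept

    def test_scale_invariance_of_ordering(self):
        rng = random.Random(9)
        cases = random_cases(rng, 25)
        qv = [rng.uniform(0, 100) for _ in ATTRS]
        order_full = [
            r.case_id
            for r in knn_retrieve(make_query(qv), cases, InferenceConfig(k=25))
        ]
        shrink = 0.37
        shrunk_cases = [
            make_case(c.case_id, [a.value * shrink for a in c.preference_vector],
                      decision=c.decision)
            for c in cases
        ]
        order_shrunk = [
            r.case_id
            for r in knn_retrieve(
                make_query([v * shrink for v in qv]), shrunk_cases,
                InferenceConfig(k=25),
            )
        ]
        assert order_full == order_shrunk


class TestWeights:
    def test_single_result_normalizes_to_one(self):
        (r,) = compute_weights([SimilarityResult("a", {}, 0.3)])
        assert r.weight == pytest.approx(1.0)

    def test_equal_distances_split_evenly(self):
        rs = compute_weights(
            [SimilarityResult("a", {}, 0.2), SimilarityResult("b", {}, 0.2)]
        )
        assert [r.weight for r in rs] == pytest.approx([0.5, 0.5])

    def test_inverse_distance_formula(self):
        distances = (0.1, 0.3, 0.6)
        eps = 1e-6
        raw = [1 / (d + eps) for d in distances]
        expected = [x / sum(raw) for x in raw]
        rs = compute_weights(
            [SimilarityResult(f"c{i}", {}, d) for i, d in enumerate(distances)]
        )
        assert [r.weight for r in rs] == pytest.approx(expected)

    def test_weights_sum_to_one_and_decrease(self):
        rng = random.Random(10)
        distances = sorted(rng.uniform(0, 2) for _ in range(7))
        rs = compute_weights(
            [SimilarityResult(f"c{i}", {}, d) for i, d in enumerate(distances)]
        )
        assert sum(r.weight for r in rs) == pytest.approx(1.0, abs=1e-9)
        assert all(a.weight >= b.weight for a, b in zip(rs, rs[1:]))


class TestRerank:
    def test_empty_retrieval_keeps_objective_order(self):
        ranked = rerank_decisions(
            ["a", "b", "c"], [], lambda cid: None
        )
        assert [d.decision for d in ranked] == ["a", "b", "c"]
        assert [d.final_rank for d in ranked] == [1, 2, 3]

    def test_unanimous_cases_promote_second_candidate(self):
        cases = {f"c{i}": make_case(f"c{i}", [50, 50, 50], decision="lumpectomy")
                 for i in range(3)}
        results = compute_weights(
            [SimilarityResult(cid, {}, 0.1 * i) for i, cid in enumerate(cases)]
        )
        ranked = rerank_decisions(
            ["mastectomy", "lumpectomy"], results, cases.__getitem__
        )
        assert ranked[0].decision == "lumpectomy"
        assert ranked[0].final_rank == 1
        assert ranked[0].original_rank == 2

    def test_higher_accumulated_weight_wins_regardless_of_objective_order(self):
        cases = {
            "c0": make_case("c0", [50] * 3, decision="b"),
            "c1": make_case("c1", [50] * 3, decision="a"),
        }
        results = [
            SimilarityResult("c0", {}, 0.0, weight=0.6),
            SimilarityResult("c1", {}, 0.0, weight=0.4),
        ]
        ranked = rerank_decisions(["a", "b"], results, cases.__getitem__)
        assert [d.decision for d in ranked] == ["b", "a"]
        assert ranked[0].experience_weight == pytest.approx(0.6)

    def test_output_is_permutation_and_weights_bounded(self):
        rng = random.Random(11)
        cases = random_cases(rng, 40)
        lookup = {c.case_id: c for c in cases}
        out = knn_retrieve(
            make_query([rng.uniform(0, 100) for _ in ATTRS]), cases,
            InferenceConfig(k=7),
        )
        objective = ["mastectomy", "lumpectomy", "surveillance", "no action"]
        ranked = rerank_decisions(objective, out.results, lookup.__getitem__)
        assert sorted(d.decision for d in ranked) == sorted(objective)
        assert sum(d.experience_weight for d in ranked) <= 1 + 1e-9


class TestWhatIf:
    def test_noop_substitution_is_identity(self):
        rng = random.Random(12)
        cases = random_cases(rng, 20)
        q = make_query([40, 60, 20])
        base = knn_retrieve(q, cases, InferenceConfig())
        alt, _ = what_if(q, "cost", 20, cases)
        assert [r.case_id for r in alt.results] == [r.case_id for r in base.results]

    def test_query_object_unchanged(self):
        q = make_query([40, 60, 20])
        what_if(q, "cost", 99, random_cases(random.Random(13), 5))
        assert q.preference_values()["cost"] == 20

    def test_moving_toward_planted_case_never_increases_its_distance(self):
        cases = [make_case("planted", [80, 10, 50])] + random_cases(
            random.Random(14), 10
        )
        q = make_query([40, 60, 20])
        before = global_distance(q, cases[0])
        out, _ = what_if(q, "pain_tolerance", 70, cases,
                         InferenceConfig(k=len(cases)))
        after = next(r.distance for r in out.results if r.case_id == "planted")
        assert after <= before

    def test_exact_match_limit_retrieves_at_zero(self):
        cases = [make_case("target", [80, 60, 20])]
        q = make_query([40, 60, 20])
        out, _ = what_if(q, "pain_tolerance", 80, cases)
        assert out.results[0].case_id == "target"
        assert out.results[0].distance == 0.0

    def test_unknown_attribute_rejected(self):
        with pytest.raises(KeyError):
            what_if(make_query([1, 2, 3]), "charisma", 50, [])


class TestArchetypeRecovery:
    def test_query_near_archetype_recovers_its_decision(self):
        plan = CaseBasePlan(
            n_cases=100,
            attribute_names=ATTRS,
            archetypes=(
                Archetype((80, 20, 50), frozenset({"breast cancer"}),
                          "mastectomy", 8.0),
                Archetype((20, 80, 50), frozenset({"breast cancer"}),
                          "lumpectomy", 8.0),
            ),
            seed=21,
        )
        cases, _ = generate_case_base(plan)
        rng = random.Random(22)
        q = make_query(
            [min(100, max(0, rng.gauss(mu, 8.0))) for mu in (80, 20, 50)]
        )
        _, ranked = recommend(q, cases, ["lumpectomy", "mastectomy"])
        assert ranked[0].decision == "mastectomy"
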