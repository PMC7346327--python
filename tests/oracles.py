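"""Independent reference computations used to check the implementation.

These deliberately avoid the code paths they verify: polarity is checked
by signed breadth-first search over the raw relation graph, and KNN by an
exhaustive distance sort computed directly from the vectors.
"""

from __future__ import annotations

import math
import random
from collections import deque

from experia.lexicon import LexiconNeighborhood, Polarity, SeedLexicon


def signed_bfs(
    seeds: dict[str, int],
    syn_edges: set[tuple[str, str]],
    ant_edges: set[tuple[str, str]],
) -> dict[str, int]:
    """Propagate +1/-1 signs from seeds; antonym edges flip the sign.

    Assumes a sign-consistent graph (no path parity conflicts). Returns
    the sign of every reachable word; unreachable words are absent.
    """
    adj: dict[str, list[tuple[str, int]]] = {}
    for a, b in syn_edges:
        adj.setdefault(a, []).append((b, +1))
        adj.setdefault(b, []).append((a, +1))
    for a, b in ant_edges:
        adj.setdefault(a, []).append((b, -1))
        adj.setdefault(b, []).append((a, -1))
    signs = dict(seeds)
    queue = deque(seeds)
    while queue:
        word = queue.popleft()
        for other, flip in adj.get(word, ()):
            if other not in signs:
                signs[other] = signs[word] * flip
                queue.append(other)
    return signs


def random_sign_graph(rng: random.Random, n_words: int):
    """A random sign-consistent lexicon graph with known ground truth.

    Words are partitioned into components; each component gets a random
    spanning tree plus a few extra edges, every edge typed synonym (same
    sign) or antonym (opposite sign) consistently with pre-assigned node
    signs, so no path ever contradicts another. Some components contain a
    seed, some none.

    Returns (seed lexicon, neighbourhood, expected sign per reachable
    word, set of words in seedless components).
    """
    words = [f"w{i}" for i in range(n_words)]
    n_comp = max(1, rng.randint(max(1, n_words // 20), max(1, n_words // 5)))
    membership = [rng.randrange(n_comp) for _ in words]
    components: dict[int, list[str]] = {}
    for w, c in zip(words, membership):
        components.setdefault(c, []).append(w)

    sign_of = {w: rng.choice((+1, -1)) for w in words}
    syn_edges: set[tuple[str, str]] = set()
    ant_edges: set[tuple[str, str]] = set()

    def connect(a: str, b: str) -> None:
        edge = (a, b) if a < b else (b, a)
        if sign_of[a] == sign_of[b]:
            syn_edges.add(edge)
        else:
            ant_edges.add(edge)

    for members in components.values():
        rng.shuffle(members)
        for i in range(1, len(members)):
            connect(members[rng.randrange(i)], members[i])
        for _ in range(len(members) // 3):
            a, b = rng.sample(members, 2) if len(members) > 1 else (None, None)
            if a is not None:
                edge = (a, b) if a < b else (b, a)
                if edge not in syn_edges and edge not in ant_edges:
                    connect(a, b)

    seeded_comps = {
        c for c in components if len(components[c]) == 0 or rng.random() < 0.7
    }
    if not seeded_comps:
        seeded_comps = {next(iter(components))}
    seed_words: dict[str, int] = {}
    for c in seeded_comps:
        for w in rng.sample(components[c], max(1, len(components[c]) // 10)):
            seed_words[w] = sign_of[w]

    pol = {+1: Polarity.POSITIVE, -1: Polarity.NEGATIVE}
    seeds = SeedLexicon({w: pol[s] for w, s in seed_words.items()})
    synonyms: dict[str, set[str]] = {}
    antonyms: dict[str, set[str]] = {}
    for a, b in syn_edges:
        synonyms.setdefault(a, set()).add(b)
    for a, b in ant_edges:
        antonyms.setdefault(a, set()).add(b)
    hood = LexiconNeighborhood(synonyms=synonyms, antonyms=antonyms)
    expected = signed_bfs(seed_words, syn_edges, ant_edges)
    unreachable = {w for w in words if w not in expected}
    return seeds, hood, expected, unreachable


def exhaustive_knn(query_values, cases, k):
    """Top-k cases by brute-force Euclidean distance on [0,1] VAS scale.

    ``cases`` maps case_id -> {attribute: value}. Returns the ordered
    list of (case_id, distance).
    """
    scored = []
    for cid, values in cases.items():
        d = math.sqrt(
            sum(((query_values[a] - values[a]) / 100.0) ** 2 for a in query_values)
        )
        scored.append((d, cid))
    scored.sort()
    return [(cid, d) for d, cid in scored[:k]]
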