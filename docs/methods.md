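# Methods

## Opinion mining

A review is an ordered list of sentences of `(surface, POS)` tokens over
a coarse tagset (NOUN, ADJ, OTHER); Penn-style tags collapse onto it on
load. The mining pipeline is staged:

**Candidate features.** Every maximal run of consecutive noun tokens is
a candidate feature (so "stereotactic biopsy" is one two-word feature,
not two). Support is the fraction of *sentences* in the corpus that
contain the phrase; sentence-level counting is the natural unit because
opinions are extracted per sentence. Association mining is realized as
per-feature support filtering: nothing downstream consumes multi-feature
itemsets, but the candidate representation (phrase → supporting sentence
set) would admit itemset expansion if it were ever needed.

**Frequent features.** Candidates with support ≥ `threshold` (default
0.1, i.e. one sentence in ten), sorted by descending support then
lexicographically. The threshold has no canonical value; 0.1 is a
starting point for corpora of tens of reviews, and the worked-example
fixture uses 0.4 so that its four repeated noun phrases are frequent in
a five-sentence review.

**Opinion words.** In each sentence, each frequent feature is paired
with the adjective at minimal token distance from the nearest edge of
the feature's span. A tie between a preceding and a following adjective
goes to the preceding one (the English premodifier convention: "radical
mastectomy" over "mastectomy ... painful" at equal distance).
`max_adjective_distance` (default unbounded) drops pairings beyond a
token window.

**Polarity propagation.** Opinion-word polarity is resolved against a
seed lexicon through a synonym/antonym neighbourhood with symmetric
relations (closure enforced at load). One lookup is one hop: a seeded
word keeps its polarity; otherwise seeded synonyms are consulted first,
then seeded antonyms with the sign flipped — the synonym-before-antonym
order is deliberate and fixed. When several seeded neighbours disagree,
the majority wins and an exact tie resolves to neutral; majority voting
is the least surprising rule for a three-way polarity and keeps the
lookup antisymmetric under global polarity inversion. The propagation
loop sweeps all unresolved words repeatedly, adding each resolved word
to the seed list, and stops when a sweep adds nothing; since the seed
list grows strictly on productive sweeps and is bounded by the
vocabulary, termination is immediate. Words never resolved are *invalid
words* and produce no opinion. On sign-consistent graphs the fixpoint
equals signed breadth-first search from the seeds (antonym edges flip
sign), which the tests verify against an independent BFS oracle.

**Sentence scoring.** `score_sentence` is a transparent seed-lexicon
vote (positive vs negative token counts; tie or no hits → neutral). It
replaces any pretrained sentence-sentiment model on purpose: results are
reproducible with no model artifact, at the cost of lexical coverage.
An optional negation toggle (off by default, to keep the mining
algorithm's semantics unmodified) flips a vote when "not"/"no"/"never"
occurs within three tokens before a seeded word; it affects sentence
scoring only, never feature-level opinion polarity.

**The shipped lexicon** has exactly 30 seed adjectives (15 positive, 15
negative) with a small synonym/antonym neighbourhood tuned to
patient-review vocabulary. It is a deliberately small, auditable
stand-in for WordNet: the file format (seeds / synonyms / antonyms
sections) is plain text, and any WordNet-derived lexicon in that format
drops in.

**Raw-text tagging.** Pre-tagged corpora are the primary input. For raw
text a small rule tagger assigns coarse tags (lexicon vocabulary and
adjectival suffixes → ADJ, stopwords → OTHER, rest → NOUN). It is a
convenience for demos, is not used by any fixture or generator (those
carry explicit tags), and should not be trusted for linguistic accuracy.

## Knowledge base

The ontology schema ships as a Turtle file with three prefixes: clinical
concepts (disease, diagnosis, therapeutic procedure), opinion-annotation
concepts (sentiment analysis, opinion, source text, described object)
and an application layer whose condition-set and opinion-set classes
derive from a common analysis-result base class. Properties that the
inference engine needs but the connected class diagram does not carry —
case identifier, decision, VAS preference attributes, text provenance —
are flagged as artifact extensions in the schema file.

Cases are emitted as URI-named individuals only (no blank nodes), with
polarity as a plain literal and VAS values as `xsd:decimal` literals in
`repr` lexical form; both choices exist so that save → load is the
*identity on triple sets*, not merely an isomorphism — the strongest
round-trip guarantee and the easiest to test. Every emitted predicate is
checked against the declared schema at emission time. Condition terms
are case-folded, whitespace-collapsed free text; mapping to a standard
clinical terminology (e.g. SNOMED CT) is out of scope. A JSON mirror of
the case store serves the inference engine's hot path; the
Turtle-vs-JSON bijection is covered by tests.

Three condition-match rules are supported: `exact`, `subset` (default:
every query condition must appear in the case — a case that experienced
*more* than the query still matches) and `jaccard` ≥ θ as a relaxation.
Conditions act as a hard pre-filter, not a distance component: retrieval
first matches conditions, then ranks by preference distance. A blended
reading (conditions contributing numerically to one global similarity)
is representable by the jaccard rule with low θ but is not the default.

## Inference engine

Preferences are VAS values in [0, 100], one per named attribute, each
with a priority rank (a permutation of 1..n). Local similarity between
two values is `1 − |a − b|/100`; global distance is the Euclidean norm
of attribute-wise differences on the normalized [0, 1] scale, aligned by
attribute name (mismatched schemas are an error, not a silent
intersection). Priority ranks can optionally weight the squared
differences (`w_i = (n − rank_i + 1)/Σ ranks`); this is off by default
so the plain Euclidean distance governs retrieval.

The k nearest condition-matched cases (default k = 5 — a retrieval
hyper-parameter with no principled value; small odd numbers behave well
for case bases of tens to hundreds of cases) are weighted by normalized
inverse distance with ε = 1e-6: an exact-match case dominates without
collapsing the weight vector to a delta. Ties in distance break by case
id, making retrieval fully deterministic. Zero condition matches is a
legitimate outcome, reported as a `no_experience` status rather than an
exception, and re-ranking then degenerates to the objective order.

Re-ranking accumulates case weights per stored decision; candidates sort
by accumulated weight, ties by original objective rank, so the output is
always a permutation of the input candidates and the experience weights
sum to at most 1. The engine never invents decisions: candidates come
from upstream objective reasoning as an ordered list and only their
order changes.

## Synthetic data

The corpus generator realizes a plan (features with planted supports,
one adjective of intended polarity per feature) into template sentences
carrying explicit POS tags, so tagger behaviour can never corrupt ground
truth. Each planted sentence holds exactly one feature with its
adjective adjacent; filler sentences contain nouns but no adjectives, so
they can become frequent features without generating opinions. Realized
supports are within one sentence of `support × n_sentences`. The
returned ground truth is exactly what mining must output at the plan's
threshold, which makes the generator itself the oracle for end-to-end
tests.

The case-base generator draws each case's archetype uniformly, then its
VAS vector from a Gaussian at the archetype centroid (standard deviation
= dispersion, truncated to [0, 100]) — a deliberately simple preference
model: unimodal per archetype, independent across attributes. Default
dispersion 5 VAS points reflects that repeated VAS elicitations from one
person typically scatter by a few points. All generators are pure
functions of plan + seed.

What the synthetic conditions do *not* emulate: real review language
(no tagger errors, no misspellings, no sarcasm), correlated preference
attributes, multi-feature sentences, and opinion words whose lexicon
paths conflict in sign. Passing tests demonstrate algorithmic
correctness under the stated model, not robustness to real
social-network text.

## Numerical and degenerate-input choices

- Weight normalization tolerance 1e-9; distances and weights are plain
  floats, no rescaling beyond the /100 VAS normalization.
- `threshold` must be in (0, 1]; an unreachable threshold yields an
  empty frequent set, not an error.
- Empty corpora and empty seed lexica are errors; empty retrievals and
  empty opinion sets are values.
- k > number of matched cases returns all matched cases.
- Duplicate case registration fails atomically (store unchanged).

## Problem sizes in the verification scripts

Oracle comparisons run on 100 random lexicon graphs (10–200 words), 100
random case bases (1–500 cases), 200 archetype-recovery trials at 100
cases each, and 50 round-trip stores (1–15 cases) — sizes at which the
brute-force oracles are instant and every structural regime (singleton
stores, k > n, seedless graph components) is exercised.

## Known limitations

- One-hop majority lookup per sweep means the resolution order of a word
  with sign-conflicting lexicon paths depends on sweep timing; the
  fixpoint is only guaranteed to equal signed BFS on conflict-free
  graphs.
- Noun-phrase chunking is "maximal noun run": premodifying adjectives
  ("radical mastectomy") are opinion words, never phrase parts, and
  determiner-split phrases are not merged.
- The rule tagger is heuristic; feed pre-tagged text for anything
  serious.
- Condition matching is set-based on normalized strings; synonymous
  condition names ("breast carcinoma" vs "breast cancer") do not match.
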