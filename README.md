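# experia

Patient-experience evidence for clinical decision support.

Evidence-based decision support derives its recommendations from trial
populations, so it says little about how individual patients *experienced*
a procedure, and nothing about how the patient in front of you weighs
pain, recovery time or cost. `experia` turns free-text patient reviews
(in the style of patient social networks) into structured, queryable
experience evidence and uses it to re-rank clinically derived candidate
decisions for a specific patient:

1. **Opinion mining** — nouns and noun phrases in POS-tagged reviews
   become candidate features; those whose *support* (fraction of
   sentences mentioning them) reaches a minimum threshold are frequent
   features; the adjective closest to a frequent feature in each sentence
   is its opinion word. Polarity comes from a 30-adjective seed lexicon
   expanded iteratively through a synonym/antonym graph: a seeded synonym
   passes its polarity on, a seeded antonym passes the opposite, and each
   resolved word joins the seed list until a sweep adds nothing. Words
   the lexicon cannot reach are invalid and yield no opinion.
2. **Patient Experience Knowledge Base (PEKB)** — mined opinions plus
   case metadata (conditions, procedure, decision, VAS preference
   vector) are mapped onto a clinical sentiment ontology (clinical
   concepts + opinion-annotation concepts + an application layer) and
   persisted as RDF/Turtle, with a JSON mirror for fast retrieval.
3. **Experience inference engine (EIE)** — a query patient's conditions
   pre-filter the stored cases; survivors are ranked by the Euclidean
   distance d(q, c) = sqrt(Σᵢ ((qᵢ − cᵢ)/100)²) between preference
   vectors of visual-analogue-scale (VAS, 0–100) values. The k nearest
   cases receive normalized inverse-distance weights
   wᵢ = (dᵢ + ε)⁻¹ / Σⱼ (dⱼ + ε)⁻¹, which are accumulated per stored
   decision to re-rank an externally supplied, already-ordered list of
   objective candidate decisions. A what-if mode recomputes everything
   with one preference value substituted.

A synthetic-data module generates every input with known ground truth —
tagged corpora with planted opinions, matching lexica, and case bases
clustered around preference archetypes — so the whole pipeline is
testable offline.

## Worked example

Mining the package's hand-tagged breast-cancer review against the
shipped lexicon:

```python
from experia import default_lexicon, mine_opinions, MiningConfig
from experia.synthetic import fig3_review

doc, _, threshold = fig3_review()
seeds, hood = default_lexicon()
opinions = mine_opinions([doc], seeds, hood, MiningConfig(threshold=threshold))
for o in sorted(opinions, key=lambda o: (o.sentence_index, o.feature)):
    print(f"{o.feature:22s} {o.opinion_word:14s} {o.polarity.value}")
```

```
pain                   excruciating   negative
stereotactic biopsy    excruciating   negative
left breast            unbearable     negative
pain                   unbearable     negative
mastectomy             radical        negative
```

"excruciating", "unbearable" and "radical" are not seeds; they resolve
through synonym links to the seeded negatives "painful", "intolerable"
and "severe". Feeding a query patient who tolerates pain well but wants
a short recovery into a 100-case synthetic base clustered around a
mastectomy-preferring and a lumpectomy-preferring archetype:

```python
outcome, ranked = recommend(patient, cases,
                            ["lumpectomy", "mastectomy", "surveillance"])
```

```
case-0002  distance=0.0690  weight=0.243
case-0047  distance=0.0760  weight=0.221
case-0079  distance=0.0905  weight=0.185
case-0082  distance=0.0930  weight=0.180
case-0006  distance=0.0978  weight=0.171

#1 mastectomy   experience_weight=1.000 (objective rank 2)
#2 lumpectomy   experience_weight=0.000 (objective rank 1)
#3 surveillance experience_weight=0.000 (objective rank 3)
```

All five nearest cases chose mastectomy, so its accumulated weight is
1.0 and it overtakes the objectively first-ranked lumpectomy; decisions
without any experience evidence keep their objective order.

The same pipeline is scriptable from the shell:

```sh
experia mine --corpus reviews.jsonl --threshold 0.1 --out opinions.tsv
experia build-pekb --opinions opinions.tsv --meta cases.json --out pekb.ttl
experia recommend --pekb pekb.ttl --patient query.json \
    --candidates decisions.json --k 5 --out ranked.json
experia what-if --pekb pekb.ttl --patient query.json \
    --candidates decisions.json --attribute pain_tolerance --value 15 \
    --out whatif.json
experia pipeline --config config.json --out-dir run/
```

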