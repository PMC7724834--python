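# locinfer

Text-based location inference for Chinese online-community posts.

`locinfer` estimates where the author of a set of short Chinese posts lives,
using only the text of the posts. It is aimed at digital-epidemiology and
computational-social-science studies of hidden populations — groups that are
hard to reach with surveys but active in online communities — where a
geographic distribution of community members must be estimated from
self-disclosed cues ("坐标成都", "北京人求扩列") rather than from profile
metadata or geotags, which are usually absent or unreliable.

## Scientific background

The pipeline treats location inference as a *set-recovery* problem. For each
user *u* there is an unknown gold set **G(u)** of administrative units
(two levels: province and prefecture-level city) and the pipeline produces an
inferred set **I(u)**. Inference proceeds in three stages:

1. **Candidate extraction.** Mentions of administrative units are found in
   preprocessed post text by one or more *components*: a gazetteer matcher
   (forward maximum matching against a bundled two-level gazetteer of Chinese
   provinces and cities, with suffix normalisation, e.g. 四川省 → 四川), a
   part-of-speech tagger adapter that keeps tokens tagged as place names
   (`ns`), and a character-level hidden-Markov-model named-entity recogniser
   decoded with the Viterbi algorithm over BMES-LOC/O tags.
2. **Context filtering.** Mentions are filtered by self-disclosure cues:
   a keyword constraint (none / weak / strong — the *strong* constraint
   requires a location keyword such as 坐标 or 定位 in the same post but
   outside the mention span) and an optional pattern filter with seven
   surface patterns (keyword-before-location, location-with-modal-particle,
   province-adjacent-to-city, and so on).
3. **Hybrid voting (HVA-LI).** When several components are configured, a
   user's final set is the *unanimous intersection* of the per-component
   sets, so the hybrid can only remove candidates, never invent them.

Accuracy is measured with four set-based ratios over the evaluated users:

| measure | per-user condition |
|---|---|
| **S** (strict) | I(u) = G(u) |
| **C** (coverage) | G(u) ⊆ I(u) |
| **T** (targeting) | I(u) ⊆ G(u) and I(u) ≠ ∅ |
| **P** (partial) | I(u) ∩ G(u) ≠ ∅ |

These satisfy S ≤ C ≤ P, S ≤ T, and per-user s = (c and t); the test suite
checks those invariants against an independent brute-force oracle.

Because no real community corpus can ship with the package, `locinfer`
includes a seeded synthetic-corpus generator that emits posts with known gold
sets, configurable contamination (travel-talk distractors, points of
interest, keyword-less posts) and aligned character-level NER training tags.
See `docs/methods.md` for the full model description and its limitations.

## Running the tests

```bash
python -m pytest -q tests/
```

The suite (159 tests, under a minute) covers unit behaviour, property-based
checks (hypothesis), oracle comparisons for the metrics and the Viterbi
decoder, and end-to-end CLI runs.

## Worked example

Simulate a 200-user corpus, infer with the hybrid of the strong-constraint
gazetteer and an HMM NER trained on the corpus's own training tags, evaluate
against the gold labels, and aggregate a province distribution:

```bash
locinfer simulate --n-users 200 --seed 7 --out demo/sim
locinfer infer --corpus demo/sim/corpus.jsonl \
    --method hybrid --components s_gazetteer,ner \
    --ner-train demo/sim/ner_train.jsonl --out demo/pred.jsonl
locinfer evaluate --pred demo/pred.jsonl --gold demo/sim/gold.jsonl \
    --out demo/metrics.json
locinfer aggregate --pred demo/pred.jsonl --level province --out demo/dist.csv
```

The evaluate step prints:

```
N_all=200 S=0.340 C=0.700 T=0.460 P=0.875
```

and the head of `demo/dist.csv` is:

```
unit,level,user_count
广东,province,30
北京,province,20
上海,province,19
四川,province,17
山东,province,17
```

The same pipeline is available as a library:

```python
from locinfer import (
    SimParams, generate_corpus, bundled_gazetteer,
    infer_user_locations, preset, compute_metrics, train_hmm,
)

gaz = bundled_gazetteer()
corpus, gold, ner_labels = generate_corpus(SimParams(n_users=200, seed=7), gaz)
hmm = train_hmm(ner_labels)
inferences = infer_user_locations(corpus, gaz, preset("s_gazetteer_ner"), hmm=hmm)
report = compute_metrics({u: i.locations for u, i in inferences.items()}, gold)
print(report.ratios())
```

Every run is deterministic: the same seed reproduces every artifact byte for
byte, and `infer` writes a `*.manifest.json` next to its output with SHA-256
digests of inputs and outputs.

## Package layout

| module | contents |
|---|---|
| `locinfer.gazetteer` | two-level gazetteer, canonicalisation, province lookup |
| `locinfer.segmentation` | forward-maximum-matching segmentation (accurate / full) |
| `locinfer.corpus` | post model, JSONL/CSV readers, text preprocessing |
| `locinfer.extract` | gazetteer / POS / HMM-NER mention extractors, Viterbi |
| `locinfer.filters` | keyword constraints (none/weak/strong), 7-mode pattern filter |
| `locinfer.pipeline` | component configs, presets, HVA-LI voting, aggregation |
| `locinfer.evaluate` | S/C/T/P metrics, gold I/O, benchmark tables |
| `locinfer.synthdata` | seeded synthetic corpus generator with gold + NER tags |
| `locinfer.cli` | `locinfer simulate / infer / evaluate / aggregate` |
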