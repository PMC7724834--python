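# Methods

This document describes the statistical and algorithmic choices behind
`locinfer`: the inference model, every tunable parameter with its default and
rationale, what the synthetic-data generator does and does not emulate, and
the package's known limitations.

## 1. Problem statement

For each user *u* with posts *d₁ … dₖ* we want the set **G(u)** of
administrative units (province and prefecture-level city) where the user
says they are located. The pipeline produces an inferred set **I(u)** of
`(canonical_name, level)` pairs drawn from a closed two-level gazetteer.
All downstream quantities (S/C/T/P accuracy, aggregated geographic
distributions) are functions of the per-user sets.

Key modelling assumptions:

- **Closed world.** Only units in the gazetteer can be inferred. Mentions of
  places outside it (districts, counties, foreign cities, POIs) are never
  candidates.
- **Self-disclosure through cues.** A location mention counts as a residence
  claim only when surrounded by disclosure cues (keywords such as 坐标/定位,
  or one of seven surface patterns). Mentions in travel or news talk should
  fail these cues.
- **Set semantics.** A user may legitimately have more than one location
  (e.g. a municipality appears at both province and city level; a user may
  name both a province and its capital). Order and multiplicity are ignored.

## 2. Pipeline stages

### 2.1 Preprocessing (`locinfer.corpus.preprocess`)

Applied in a fixed order: URL removal (`https?://…`, `www.…`), then removal
of punctuation/symbols/separators/control characters (Unicode categories P,
S, Z, C), then stopword removal. Stopwords are removed *as segmented tokens*,
not as raw substrings: the text is segmented by forward maximum matching over
the stopword list plus a `protect` dictionary (normally the gazetteer
surfaces), so a stopword character sequence inside a protected word is never
deleted (e.g. a hypothetical stopword 都 must not split 成都). Removal is
iterated to a fixed point, which makes `preprocess` idempotent — a property
the test suite checks.

### 2.2 Segmentation (`locinfer.segmentation`)

Dictionary-driven forward maximum matching (FMM) with two modes:

- `accurate` — a left-to-right partition, always preferring the longest
  dictionary word at each position; non-dictionary characters become
  single-character tokens.
- `full` — every dictionary substring occurrence plus all unigrams; used
  where recall matters more than a clean partition (pattern scanning).

FMM is implemented in-package rather than through an external statistical
segmenter so that segmentation is fully deterministic, dependency-free and
auditable; the cost is that genuinely ambiguous segmentations are resolved
greedily (see Limitations).

### 2.3 Gazetteer (`locinfer.gazetteer`)

A CSV of 34 province-level units and ~84 major prefecture-level cities with
aliases. Canonicalisation is NFC normalisation followed by stripping at most
one administrative suffix, longest suffix first (特别行政区, 自治区, 省, 市),
so 四川省 → 四川 but a bare 省 is never stripped twice. The four
municipalities (北京, 上海, 天津, 重庆) and the two special administrative
regions appear at *both* levels with themselves as parent province, which
keeps `province_of` total and makes dual-level gold sets well defined.

### 2.4 Extractors (`locinfer.extract`)

- **Gazetteer extractor** — FMM over the gazetteer surfaces; each matched
  surface yields the unit(s) it canonicalises to.
- **POS extractor** — an adapter around any tagger satisfying the `PosTagger`
  protocol; tokens tagged `ns` (place name) that canonicalise in the
  gazetteer become mentions. The bundled `BaselinePosTagger` tags exactly the
  gazetteer surfaces as `ns`, making the baseline POS component behave like
  the gazetteer component while leaving the interface open for a real tagger.
- **HMM NER extractor** — a character-level hidden Markov model over the
  five states B-LOC, M-LOC, E-LOC, S-LOC, O. Decoded spans that canonicalise
  in the gazetteer become mentions.

HMM details:

- **Structural zeros.** Only linguistically valid transitions are allowed
  (e.g. B-LOC can only go to M-LOC or E-LOC; a sequence can only start with
  B-LOC, S-LOC or O). Disallowed transitions have probability exactly zero
  rather than a smoothed small value, so the decoder can never emit an
  ill-formed tag sequence.
- **Smoothing.** Add-one smoothing over the *allowed* transition cells and
  over the emission vocabulary plus one `<UNK>` slot per state. Unseen
  characters fall back to the `<UNK>` emission probability.
- **Decoding.** Viterbi in log space. Ties are broken by a fixed state
  order, so decoding is deterministic; the test suite and the acceptance
  script verify the decoded path is always among the exact argmax paths found
  by exhaustive enumeration.
- The model is a *single-layer* character HMM: one model tags raw characters
  directly, without a cascaded word-level second stage. This keeps training
  data requirements minimal (the synthetic NER tags are enough) and the
  decoder exactly testable against enumeration.

### 2.5 Filters (`locinfer.filters`)

**Keyword constraint.** The base lexicon has eight words
(坐标, 定位, 在, 是, 同, 求, 人, 交友), optionally augmented with two more
(本地, 家乡). Three levels:

- `none` — no filtering.
- `weak` — keep a user's mentions if *any* keyword occurs anywhere in *any*
  of that user's posts.
- `strong` — keep a mention only if a keyword occurs in the *same post* and
  its occurrence is character-disjoint from the mention span (so the 在 in
  在成都 counts, but a keyword character inside the place name itself does
  not).

Strong ⊆ weak ⊆ none per user, by construction; a property test checks this
monotonicity on 1000 simulated users.

**Pattern filter.** Seven surface patterns, matched in the cleaned text with
a ±2-character adjacency window around the mention: keyword-before-location,
location-before-keyword, global keyword elsewhere in the post, the location
standing alone as the whole post, the location alone with trailing
punctuation in the raw text, location followed by a modal particle
(吗/呢/啊/哦/呀), and a province immediately adjacent to one of its own
cities (which validates both mentions). The 2-character window is the
smallest window that tolerates one function word between cue and mention
while still rejecting cues in a different clause.

### 2.6 Hybrid voting (`locinfer.pipeline`)

With *k* ≥ 2 configured components, each component runs end to end
(extraction, then its own keyword constraint, then the optional pattern
restriction), producing a per-user set; the final set is the unanimous
intersection. Consequences, all covered by tests: the hybrid is contained in
every component, voting is idempotent and commutative, and adding a component
can only shrink (never grow) a user's set.

### 2.7 Metrics (`locinfer.evaluate`)

Per-user flags: s ⇔ I = G; c ⇔ G ⊆ I; t ⇔ I ⊆ G **and** I ≠ ∅; p ⇔
I ∩ G ≠ ∅. The extra non-emptiness condition on *t* prevents the degenerate
"predict nothing for everyone" strategy from achieving perfect targeting;
without it T would be trivially gameable. Ratios are flag counts over all
evaluated users. Empty gold sets and users missing from the predictions are
hard errors, not silent zeros.

## 3. Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| `SimParams.n_users` | — (required) | study size is caller's choice |
| `SimParams.posts_per_user` | 3 | short posting histories are the hard, typical case |
| `SimParams.p_multi_location` | 0.15 | a minority of users disclose two locations |
| `SimParams.p_keyword` | 0.9 | most, not all, disclosures carry an explicit cue |
| `SimParams.p_distractor` | 0.3 | travel/news mentions are common but not dominant |
| `SimParams.p_poi` | 0.1 | occasional non-gazetteer place names |
| `SimParams.seed` | 0 | any value in [0, 2³¹) |
| keyword constraint | `none` | filtering is opt-in; presets choose per design |
| adjacency window | 2 chars | one function word of slack, see §2.5 |
| suffix stripping | one suffix, longest first | prevents over-stripping of short names |
| HMM smoothing | add-one | tiny training sets; zero-free within allowed cells |
| segmentation mode | `accurate` | partition semantics for extraction; `full` for pattern scanning |

City sampling weights (`DEFAULT_CITY_WEIGHTS`, 35 cities) are fixed integers
that skew mass toward large cities so aggregated distributions have a
realistic head-heavy shape; a χ² test in the suite confirms the generator
matches them.

## 4. What the generator emulates — and what it does not

Emulated:

- self-disclosure posts built from the seven pattern modes, with and without
  keywords (`p_keyword`);
- contamination: distractor mentions of *non-gold* gazetteer units in
  travel/news templates (`p_distractor`), non-gazetteer POI mentions
  (`p_poi`), and filler text;
- multi-location users (`p_multi_location`) and dual-level gold sets for
  municipalities; when the province-with-city pattern is used the parent
  province joins the gold set;
- raw text with URLs and punctuation, whose preprocessed form is emitted
  alongside as `clean_text` (the suite verifies `preprocess(raw) == clean`);
- aligned character-level NER training tags in which every injected place
  span — gold, distractor, or POI — is labelled LOC.

Per-user randomness comes from `np.random.default_rng([seed, user_index])`,
so corpora are prefix-stable: growing `n_users` never changes existing users.

Not emulated: real lexical diversity (a fixed template inventory), typos and
nonstandard variants, code-switching, sarcasm or negated disclosures
("不在北京"), temporal location changes, platform artifacts (replies,
hashtags, emoji beyond what punctuation stripping removes), and any
correlation between location and writing style. Benchmark numbers computed
on synthetic corpora therefore characterise the *pipeline's behaviour under
the generator's noise model*, not expected accuracy on real community data.

Template hygiene is enforced by tests: no fixed template fragment contains a
gazetteer surface, a stopword, or anything preprocessing would alter, so gold
labels and NER tag offsets cannot drift.

## 5. Numerical and implementation choices

- All probabilities are kept as log-probabilities; impossible events are
  −∞, never a tiny float, so structural zeros survive arithmetic.
- All set outputs are serialised in sorted order and files are written in
  UTF-8 with `sort_keys=True`, making every artifact byte-reproducible; the
  acceptance script and the suite both check rerun byte-identity.
- FMM tie-breaking (longest match, then leftmost) and Viterbi tie-breaking
  (fixed state order) are deterministic by construction.
- Metrics are exact integer counts divided once at the end; no floating-point
  accumulation is involved.

## 6. Limitations

- **Greedy segmentation.** FMM resolves overlap ambiguity greedily; a
  statistical segmenter could recover crossing matches that FMM misses.
- **Baseline POS tagger.** The bundled tagger is intentionally trivial; the
  POS component adds value only when a real tagger is plugged in through the
  `PosTagger` protocol.
- **Single-layer HMM.** Character HMMs have no access to word-level features;
  the NER component trained on synthetic tags overfits the template
  inventory and should be retrained on annotated data for real corpora.
- **Closed gazetteer, two levels.** County-level and informal region names
  are out of scope; extending the CSV is the supported path.
- **Unanimous voting is conservative.** Intersection voting trades coverage
  (C) for targeting (T) by design; it cannot recover a unit any single
  component misses.
- **Synthetic benchmarks only.** No claims are made about accuracy on real
  platforms; all shipped numbers are recomputed from seeds by
  `scripts/acceptance.py` and the test suite.
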