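"""Candidate place-mention extraction.

Three extractor families produce :class:`Mention` objects from a corpus:

* **gazetteer** — dictionary segmentation followed by gazetteer lookup;
* **pos** — a part-of-speech adapter; tokens tagged ``ns`` (place name)
  that resolve against the gazetteer become mentions.  The packaged
  baseline tagger assigns ``ns`` exactly to gazetteer surface forms;
* **ner** — a character-level hidden Markov model over the BMES-LOC/O tag
  set, decoded with Viterbi; decoded LOC spans that resolve against the
  gazetteer become mentions.

All extractors gate their output on gazetteer canonicalization because the
pipeline infers locations at province/city level only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence, Union

from .corpus import UserCorpus
from .errors import ExtractorError, TagValidationError, TrainingError
from .gazetteer import CITY, PROVINCE, AdminUnit, Gazetteer
from .segmentation import ACCURATE, Token, segment

SOURCE_GAZETTEER = "gazetteer"
SOURCE_POS = "pos"
SOURCE_NER = "ner"

LEVEL_FILTERS = (PROVINCE, CITY, "both")

# --------------------------------------------------------------------------
# Mention
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Mention:
    """One candidate place occurrence in a specific post.

    Offsets are 0-based, end-exclusive character positions in the post's
    ``clean_text``.  ``units`` is the non-empty set of gazetteer units the
    surface resolves to; ``modes`` records pattern-filter matches, if any.
    """

    user_id: str
    post_id: str
    start: int
    end: int
    surface: str
    units: frozenset
    source: str
    modes: tuple = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("mention offsets must satisfy 0 <= start < end")
        if not self.units:
            raise ValueError("mention must resolve to at least one unit")


def _level_ok(unit: AdminUnit, level_filter: str) -> bool:
    return level_filter == "both" or unit.level == level_filter


def _mentions_from_tokens(
    post, tokens: Iterable[Token], gaz: Gazetteer, source: str, level_filter: str = "both"
) -> list[Mention]:
    out = []
    for tok in tokens:
        units = frozenset(
            u for u in gaz.canonicalize(tok.text) if _level_ok(u, level_filter)
        )
        if units:
            out.append(
                Mention(
                    user_id=post.user_id,
                    post_id=post.post_id,
                    start=tok.start,
                    end=tok.end,
                    surface=tok.text,
                    units=units,
                    source=source,
                )
            )
    return out


# --------------------------------------------------------------------------
# Gazetteer extractor
# --------------------------------------------------------------------------


def extract_gazetteer(
    corpus: UserCorpus,
    gaz: Gazetteer,
    mode: str = ACCURATE,
    level_filter: str = "both",
    base_lexicon: Iterable[str] = (),
) -> list[Mention]:
    """Segment each post and emit a mention per gazetteer-resolvable token.

    The segmentation dictionary is the union of all gazetteer surface forms
    and ``base_lexicon`` (typically context keywords and common words, which
    keep the matcher from splitting them into stray characters).
    """
    if level_filter not in LEVEL_FILTERS:
        raise ValueError(f"invalid level filter {level_filter!r}")
    dictionary = gaz.surfaces() | {w for w in base_lexicon if w}
    mentions: list[Mention] = []
    for post in corpus.iter_posts():
        tokens = segment(post.clean_text, dictionary, mode)
        seen: set[tuple[int, int]] = set()
        for tok in tokens:
            if (tok.start, tok.end) in seen:
                continue
            seen.add((tok.start, tok.end))
            mentions.extend(
                _mentions_from_tokens(post, [tok], gaz, SOURCE_GAZETTEER, level_filter)
            )
    return mentions


# --------------------------------------------------------------------------
# Part-of-speech extractor
# --------------------------------------------------------------------------


class PosTagger(Protocol):
    """Adapter protocol: tokenize a string and tag each token."""

    def tag(self, text: str) -> Sequence[tuple[Token, str]]: ...


class BaselinePosTagger:
    """Dictionary-backed tagger: gazetteer surfaces are ``ns``, rest ``x``.

    Stands behind the same interface a full Chinese tagger (e.g. Jieba's
    POS mode) would implement, so a real tagger can be plugged in.
    """

    def __init__(self, gaz: Gazetteer, extra_words: Iterable[str] = ()):
        self._gaz = gaz
        self._dictionary = gaz.surfaces() | {w for w in extra_words if w}

    def tag(self, text: str) -> list[tuple[Token, str]]:
        tokens = segment(text, self._dictionary, ACCURATE)
        return [
            (tok, "ns" if self._gaz.canonicalize(tok.text) else "x")
            for tok in tokens
        ]


def extract_pos(
    corpus: UserCorpus,
    tagger: Optional[PosTagger] = None,
    gaz: Optional[Gazetteer] = None,
) -> list[Mention]:
    """Emit a mention per ``ns``-tagged token that resolves in the gazetteer."""
    if gaz is None:
        raise ValueError("extract_pos requires a gazetteer")
    if tagger is None:
        tagger = BaselinePosTagger(gaz)
    mentions: list[Mention] = []
    for post in corpus.iter_posts():
        try:
            tagged = tagger.tag(post.clean_text)
        except Exception as exc:  # adapter failure
            raise ExtractorError(f"POS tagger failed on post {post.post_id!r}: {exc}") from exc
        ns_tokens = [tok for tok, tag in tagged if tag == "ns"]
        mentions.extend(_mentions_from_tokens(post, ns_tokens, gaz, SOURCE_POS))
    return mentions


# --------------------------------------------------------------------------
# Character-level HMM (BMES-LOC / O) and Viterbi decoding
# --------------------------------------------------------------------------

STATES = ("B-LOC", "M-LOC", "E-LOC", "S-LOC", "O")
UNK = "<UNK>"

# Structurally possible transitions for a well-formed BMES span grammar.
ALLOWED_TRANSITIONS: dict[str, tuple[str, ...]] = {
    "B-LOC": ("M-LOC", "E-LOC"),
    "M-LOC": ("M-LOC", "E-LOC"),
    "E-LOC": ("B-LOC", "S-LOC", "O"),
    "S-LOC": ("B-LOC", "S-LOC", "O"),
    "O": ("B-LOC", "S-LOC", "O"),
}
ALLOWED_INITIAL = ("B-LOC", "S-LOC", "O")

NEG_INF = float("-inf")


@dataclass
class HmmModel:
    """Character-emission HMM over the BMES-LOC/O tag set, in log space.

    Structural zeros (transitions that would break the span grammar, e.g.
    O→M-LOC) are kept at probability zero; everything else is estimated by
    maximum likelihood with add-one smoothing over the training vocabulary
    plus one unseen-character pseudo-symbol.
    """

    states: tuple = STATES
    initial_logprob: dict = field(default_factory=dict)
    transition_logprob: dict = field(default_factory=dict)
    emission_logprob: dict = field(default_factory=dict)
    vocabulary: frozenset = field(default_factory=frozenset)

    def emission(self, state: str, char: str) -> float:
        row = self.emission_logprob[state]
        return row.get(char, row[UNK])

    def validate(self, tol: float = 1e-9) -> None:
        """Check every probability row sums to 1 and zeros are structural."""

        def check_row(logprobs: Iterable[float], what: str) -> None:
            total = sum(math.exp(lp) for lp in logprobs if lp > NEG_INF)
            if abs(total - 1.0) > tol:
                raise ValueError(f"{what} sums to {total}, not 1")

        check_row(
            (self.initial_logprob.get(s, NEG_INF) for s in self.states), "initial row"
        )
        for s in self.states:
            if self.initial_logprob.get(s, NEG_INF) > NEG_INF and s not in ALLOWED_INITIAL:
                raise ValueError(f"initial probability leaked into {s}")
            check_row(self.transition_logprob[s].values(), f"transition row {s}")
            for t, lp in self.transition_logprob[s].items():
                if lp > NEG_INF and t not in ALLOWED_TRANSITIONS[s]:
                    raise ValueError(f"structural zero violated: {s}->{t}")
            check_row(self.emission_logprob[s].values(), f"emission row {s}")

    # ---- serialization ----

    def to_json(self) -> str:
        payload = {
            "states": list(self.states),
            "initial_logprob": self.initial_logprob,
            "transition_logprob": self.transition_logprob,
            "emission_logprob": self.emission_logprob,
            "vocabulary": sorted(self.vocabulary),
        }
        return json.dumps(payload, ensure_ascii=False, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "HmmModel":
        payload = json.loads(text)
        return cls(
            states=tuple(payload["states"]),
            initial_logprob=payload["initial_logprob"],
            transition_logprob=payload["transition_logprob"],
            emission_logprob=payload["emission_logprob"],
            vocabulary=frozenset(payload["vocabulary"]),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "HmmModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def validate_tags(chars: str, tags: Sequence[str], sample_id: str = "") -> None:
    """Reject length mismatches and tag sequences outside the span grammar."""
    label = f"sample {sample_id}" if sample_id else "sample"
    if len(chars) != len(tags):
        raise TagValidationError(f"{label}: {len(chars)} chars but {len(tags)} tags")
    if not tags:
        return
    for tag in tags:
        if tag not in STATES:
            raise TagValidationError(f"{label}: unknown tag {tag!r}")
    if tags[0] not in ALLOWED_INITIAL:
        raise TagValidationError(f"{label}: sequence starts with {tags[0]}")
    for prev, cur in zip(tags, tags[1:]):
        if cur not in ALLOWED_TRANSITIONS[prev]:
            raise TagValidationError(f"{label}: invalid transition {prev}->{cur}")
    if tags[-1] in ("B-LOC", "M-LOC"):
        raise TagValidationError(f"{label}: sequence ends mid-span ({tags[-1]})")


def train_hmm(labeled: Sequence[tuple[str, Sequence[str]]]) -> HmmModel:
    """Estimate an :class:`HmmModel` from (characters, tags) pairs.

    Add-one smoothing is applied over the structurally allowed transition
    and initial cells and, for emissions, over the observed character
    vocabulary plus the unseen-character pseudo-symbol.
    """
    samples = [s for s in labeled if s[0]]
    if not samples:
        raise TrainingError("empty training set")

    init_counts = {s: 0 for s in ALLOWED_INITIAL}
    trans_counts = {s: {t: 0 for t in ALLOWED_TRANSITIONS[s]} for s in STATES}
    emit_counts: dict[str, dict[str, int]] = {s: {} for s in STATES}
    vocab: set[str] = set()

    for idx, (chars, tags) in enumerate(samples):
        validate_tags(chars, tags, sample_id=str(idx))
        init_counts[tags[0]] += 1
        for prev, cur in zip(tags, tags[1:]):
            trans_counts[prev][cur] += 1
        for ch, tag in zip(chars, tags):
            emit_counts[tag][ch] = emit_counts[tag].get(ch, 0) + 1
            vocab.add(ch)

    def smooth_row(counts: dict) -> dict:
        total = sum(counts.values()) + len(counts)
        return {k: math.log((c + 1) / total) for k, c in counts.items()}

    initial = {s: NEG_INF for s in STATES}
    initial.update(smooth_row(init_counts))

    transition = {s: {t: NEG_INF for t in STATES} for s in STATES}
    for s in STATES:
        transition[s].update(smooth_row(trans_counts[s]))

    emission = {}
    symbols = sorted(vocab) + [UNK]
    for s in STATES:
        counts = emit_counts[s]
        total = sum(counts.values()) + len(symbols)
        emission[s] = {
            sym: math.log((counts.get(sym, 0) + 1) / total) for sym in symbols
        }

    return HmmModel(
        states=STATES,
        initial_logprob=initial,
        transition_logprob=transition,
        emission_logprob=emission,
        vocabulary=frozenset(vocab),
    )


def viterbi_decode(text: str, model: HmmModel) -> list[str]:
    """Maximum-log-probability tag path; ties resolved by fixed state order."""
    if not text:
        return []
    states = model.states
    score = {
        s: model.initial_logprob.get(s, NEG_INF) + model.emission(s, text[0])
        for s in states
    }
    back: list[dict[str, str]] = []
    for ch in text[1:]:
        new_score: dict[str, float] = {}
        pointers: dict[str, str] = {}
        for cur in states:
            best_prev, best = None, NEG_INF
            for prev in states:  # fixed order breaks ties toward earlier state
                cand = score[prev] + model.transition_logprob[prev].get(cur, NEG_INF)
                if cand > best:
                    best, best_prev = cand, prev
            new_score[cur] = best + model.emission(cur, ch)
            pointers[cur] = best_prev if best_prev is not None else states[0]
        score = new_score
        back.append(pointers)
    last, best = states[0], NEG_INF
    for s in states:
        if score[s] > best:
            best, last = score[s], s
    path = [last]
    for pointers in reversed(back):
        path.append(pointers[path[-1]])
    path.reverse()
    return path


def loc_spans(tags: Sequence[str]) -> list[tuple[int, int]]:
    """Contiguous LOC spans (start, end) from a BMES tag sequence.

    A trailing B/M run without its closing E (possible because decoding
    imposes no end-state distribution) is still returned as a span; the
    gazetteer gate downstream decides whether it resolves.
    """
    spans: list[tuple[int, int]] = []
    start: Optional[int] = None
    for i, tag in enumerate(tags):
        if tag == "S-LOC":
            if start is not None:
                spans.append((start, i))
                start = None
            spans.append((i, i + 1))
        elif tag == "B-LOC":
            if start is not None:
                spans.append((start, i))
            start = i
        elif tag == "E-LOC":
            spans.append((start if start is not None else i, i + 1))
            start = None
        elif tag == "O":
            if start is not None:
                spans.append((start, i))
                start = None
    if start is not None:
        spans.append((start, len(tags)))
    return spans


def extract_ner(
    corpus: UserCorpus, model: HmmModel, gaz: Gazetteer
) -> list[Mention]:
    """Viterbi-decode each post; resolvable LOC spans become mentions."""
    mentions: list[Mention] = []
    for post in corpus.iter_posts():
        tags = viterbi_decode(post.clean_text, model)
        tokens = [
            Token(post.clean_text[a:b], a, b) for a, b in loc_spans(tags)
        ]
        mentions.extend(_mentions_from_tokens(post, tokens, gaz, SOURCE_NER))
    return mentions
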