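"""Context-keyword and syntax-pattern filtering of candidate mentions.

A place name in a dating-community post is far more likely to be the
author's own location when it co-occurs with a short context keyword
(坐标 "coordinate", 在 "in", 交友 "dating", ...).  Two filters exploit this:

* :func:`keyword_filter` keeps mentions by keyword co-occurrence, under a
  weak (any keyword anywhere in the user's posts) or strong (keyword in the
  same post as the mention) constraint;
* :func:`pattern_filter` keeps only mentions whose post matches one of
  seven syntax patterns commonly used when people state where they are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

from .corpus import Post, UserCorpus, strip_punctuation
from .errors import ConsistencyError
from .extract import SOURCE_GAZETTEER, Mention
from .gazetteer import CITY, Gazetteer
from .segmentation import segment

# The eight-keyword base lexicon used by the context-keyword filter.
BASE_KEYWORDS = ("坐标", "定位", "在", "是", "同", "求", "人", "交友")

# Positional keyword classes used by the pattern filter.
FORMER_KEYWORDS = ("坐标", "定位", "同", "在", "从", "去", "是", "也是", "求", "就是", "大")
LATER_KEYWORDS = ("人", "上学", "上班", "有", "有吗", "附近", "的", "滴", "是", "加")
GLOBAL_KEYWORDS = ("交友", "大学", "学院", "公司", "同城", "私聊")

# Ten common additions for keyword-augmentation experiments.
DEFAULT_AUGMENTED = ("上学", "上班", "工作", "朋友", "学校", "附近", "有吗", "私聊", "同城", "来")

MODAL_PARTICLES = ("吗", "呢", "啊", "哦", "呀")

CONSTRAINT_NONE = "none"
CONSTRAINT_WEAK = "weak"
CONSTRAINT_STRONG = "strong"
CONSTRAINT_MODES = (CONSTRAINT_NONE, CONSTRAINT_WEAK, CONSTRAINT_STRONG)

PATTERN_MODES = (
    "former_keyword",
    "later_keyword",
    "global_keyword",
    "individual_location",
    "individual_with_punct",
    "location_with_modal",
    "province_with_city",
)

# Former/later keywords must sit within this many characters of the
# mention boundary to count as adjacent.
ADJACENCY_WINDOW = 2


@dataclass(frozen=True)
class KeywordLexicon:
    base: tuple = BASE_KEYWORDS
    former: tuple = FORMER_KEYWORDS
    later: tuple = LATER_KEYWORDS
    global_: tuple = GLOBAL_KEYWORDS
    augmented: tuple = ()

    @property
    def active(self) -> tuple:
        """Keywords used by the co-occurrence filter: base plus augmented."""
        return self.base + tuple(k for k in self.augmented if k not in self.base)

    def all_words(self) -> set[str]:
        """Every lexicon word (segmentation dictionary aid)."""
        return set(self.base) | set(self.former) | set(self.later) | set(
            self.global_
        ) | set(self.augmented) | set(MODAL_PARTICLES)

    def with_augmented(self, extra: Iterable[str] = DEFAULT_AUGMENTED) -> "KeywordLexicon":
        return replace(self, augmented=tuple(extra))

    def to_json(self) -> str:
        return json.dumps(
            {
                "base": list(self.base),
                "former": list(self.former),
                "later": list(self.later),
                "global": list(self.global_),
                "augmented": list(self.augmented),
            },
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "KeywordLexicon":
        d = json.loads(text)
        return cls(
            base=tuple(d.get("base", BASE_KEYWORDS)),
            former=tuple(d.get("former", FORMER_KEYWORDS)),
            later=tuple(d.get("later", LATER_KEYWORDS)),
            global_=tuple(d.get("global", GLOBAL_KEYWORDS)),
            augmented=tuple(d.get("augmented", ())),
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "KeywordLexicon":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def _occurrences(haystack: str, needle: str) -> list[tuple[int, int]]:
    spans = []
    i = haystack.find(needle)
    while i != -1:
        spans.append((i, i + len(needle)))
        i = haystack.find(needle, i + 1)
    return spans


def _keyword_outside_span(post_text: str, keywords: Sequence[str], start: int, end: int) -> bool:
    for kw in keywords:
        for a, b in _occurrences(post_text, kw):
            if b <= start or a >= end:  # disjoint from the mention span
                return True
    return False


def keyword_filter(
    mentions: Sequence[Mention],
    corpus: UserCorpus,
    lex: KeywordLexicon = KeywordLexicon(),
    mode: str = CONSTRAINT_NONE,
) -> list[Mention]:
    """Filter mentions by context-keyword co-occurrence.

    ``none`` returns the input unchanged.  ``weak`` keeps all of a user's
    mentions iff any keyword occurs in any of that user's posts.  ``strong``
    keeps a mention iff a keyword occurs in the same post, with the keyword
    characters lying outside the mention's own span (so 人 inside a place
    name cannot license itself).
    """
    if mode not in CONSTRAINT_MODES:
        raise ValueError(f"unknown constraint mode {mode!r}")
    for m in mentions:
        if corpus.get(m.user_id, m.post_id) is None:
            raise ConsistencyError(
                f"mention references unknown post ({m.user_id}, {m.post_id})"
            )
    if mode == CONSTRAINT_NONE:
        return list(mentions)
    keywords = lex.active
    if mode == CONSTRAINT_WEAK:
        users_with_kw = {
            uid
            for uid, posts in corpus.users.items()
            if any(kw in p.clean_text for p in posts for kw in keywords)
        }
        return [m for m in mentions if m.user_id in users_with_kw]
    # strong
    kept = []
    for m in mentions:
        post = corpus.get(m.user_id, m.post_id)
        if _keyword_outside_span(post.clean_text, keywords, m.start, m.end):
            kept.append(m)
    return kept


# --------------------------------------------------------------------------
# Pattern recognition
# --------------------------------------------------------------------------


def _match_modes(
    post: Post,
    token_start: int,
    token_end: int,
    surface: str,
    units: frozenset,
    gaz: Gazetteer,
    lex: KeywordLexicon,
    modal_particles: Sequence[str],
) -> list[str]:
    text = post.clean_text
    modes = []

    for kw in lex.former:
        if any(
            0 <= token_start - b <= ADJACENCY_WINDOW for _, b in _occurrences(text, kw)
        ):
            modes.append("former_keyword")
            break
    for kw in lex.later:
        if any(
            0 <= a - token_end <= ADJACENCY_WINDOW for a, _ in _occurrences(text, kw)
        ):
            modes.append("later_keyword")
            break
    if any(kw in text for kw in lex.global_):
        modes.append("global_keyword")
    if text == surface:
        modes.append("individual_location")
    raw_depunct = strip_punctuation(post.raw_text)
    if raw_depunct == surface and post.raw_text != raw_depunct:
        modes.append("individual_with_punct")
    if text[token_end : token_end + 1] in modal_particles:
        modes.append("location_with_modal")

    # province_with_city: this token is a city adjacent to its own parent
    # province (either order), or a province adjacent to one of its cities.
    for unit in units:
        if unit.level == CITY:
            parent = gaz.province_of(unit)
            before = text[:token_start]
            after = text[token_end:]
            if any(before.endswith(s) for s in parent.surfaces) or any(
                after.startswith(s) for s in parent.surfaces
            ):
                modes.append("province_with_city")
                break
    return modes


def pattern_filter(
    corpus: UserCorpus,
    gaz: Gazetteer,
    lex: KeywordLexicon = KeywordLexicon(),
    modal_particles: Sequence[str] = MODAL_PARTICLES,
) -> list[Mention]:
    """Emit mentions only where a post realizes at least one syntax pattern.

    Candidate place tokens come from accurate-mode segmentation over the
    gazetteer's surface forms.  When the province-with-city pattern fires,
    both the province and the city mention are emitted.  Each mention
    records every pattern mode it matched.
    """
    dictionary = gaz.surfaces() | lex.all_words()
    mentions: list[Mention] = []
    for post in corpus.iter_posts():
        candidates = []
        for tok in segment(post.clean_text, dictionary, "accurate"):
            units = gaz.canonicalize(tok.text)
            if units:
                candidates.append((tok, units))
        pending = []
        province_partner: set[int] = set()
        for idx, (tok, units) in enumerate(candidates):
            modes = _match_modes(
                post, tok.start, tok.end, tok.text, units, gaz, lex, modal_particles
            )
            if "province_with_city" in modes:
                # mark the adjacent province token(s) as pattern partners
                for jdx, (tok2, units2) in enumerate(candidates):
                    if jdx == idx:
                        continue
                    if tok2.end == tok.start or tok2.start == tok.end:
                        parents = {
                            gaz.province_of(u) for u in units if u.level == CITY
                        }
                        if units2 & {p for p in parents}:
                            province_partner.add(jdx)
            pending.append((tok, units, modes))
        for idx, (tok, units, modes) in enumerate(pending):
            if idx in province_partner and "province_with_city" not in modes:
                modes = modes + ["province_with_city"]
            if not modes:
                continue
            mentions.append(
                Mention(
                    user_id=post.user_id,
                    post_id=post.post_id,
                    start=tok.start,
                    end=tok.end,
                    surface=tok.text,
                    units=units,
                    source=SOURCE_GAZETTEER,
                    modes=tuple(modes),
                )
            )
    return mentions
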