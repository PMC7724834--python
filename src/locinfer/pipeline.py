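"""Pipeline composition: extractors + filters → per-user location sets.

The hybrid voting scheme (HVA-LI) runs two or more extractor/filter
components independently over the same corpus and keeps, per user, only
the locations every component agrees on (unanimous set intersection).
``S-Gazetteer`` names the gazetteer extractor combined with the
strong-constraint keyword filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .corpus import UserCorpus
from .errors import ConfigurationError
from .extract import (
    BaselinePosTagger,
    HmmModel,
    Mention,
    extract_gazetteer,
    extract_ner,
    extract_pos,
)
from .filters import (
    CONSTRAINT_NONE,
    CONSTRAINT_STRONG,
    KeywordLexicon,
    keyword_filter,
    pattern_filter,
)
from .gazetteer import CITY, PROVINCE, AdminUnit, Gazetteer
from .segmentation import ACCURATE

METHODS = ("gazetteer", "pos", "ner", "hybrid")


@dataclass(frozen=True)
class ComponentConfig:
    """One voting component: an extractor plus its own filter settings."""

    method: str
    constraint: str = CONSTRAINT_NONE
    pattern: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("gazetteer", "pos", "ner"):
            raise ConfigurationError(f"unknown component method {self.method!r}")


@dataclass(frozen=True)
class PipelineConfig:
    method: str = "gazetteer"
    components: tuple = ()
    seg_mode: str = ACCURATE
    constraint: str = CONSTRAINT_NONE
    pattern_filter: bool = False
    level_filter: str = "both"
    augment_keywords: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.method == "hybrid" and len(set(self.components)) < 2:
            raise ConfigurationError("hybrid requires at least 2 distinct components")

    def resolved_components(self) -> tuple:
        if self.method == "hybrid":
            return tuple(self.components)
        return (
            ComponentConfig(
                method=self.method,
                constraint=self.constraint,
                pattern=self.pattern_filter,
            ),
        )


def parse_component(name: str) -> ComponentConfig:
    """Parse a component name like ``gazetteer``, ``s_gazetteer`` or ``ner``.

    The ``s_`` prefix requests the strong-constraint keyword filter on that
    component.
    """
    name = name.strip().lower()
    strong = name.startswith("s_") or name.startswith("s-")
    if strong:
        name = name[2:]
    if name in ("pt", "pos_tagging"):
        name = "pos"
    return ComponentConfig(
        method=name, constraint=CONSTRAINT_STRONG if strong else CONSTRAINT_NONE
    )


def preset(name: str, seed: int = 0) -> PipelineConfig:
    """Named algorithm variants used in the benchmark comparisons."""
    name = name.strip().lower().replace("&", "_").replace(" ", "")
    table = {
        "gazetteer": PipelineConfig(method="gazetteer", seed=seed),
        "pos": PipelineConfig(method="pos", seed=seed),
        "ner": PipelineConfig(method="ner", seed=seed),
        "gazetteer_context_weak": PipelineConfig(
            method="gazetteer", constraint="weak", seed=seed
        ),
        "s_gazetteer": PipelineConfig(
            method="gazetteer", constraint=CONSTRAINT_STRONG, seed=seed
        ),
        "gazetteer_pattern": PipelineConfig(
            method="gazetteer", pattern_filter=True, seed=seed
        ),
        "s_gazetteer_pt": PipelineConfig(
            method="hybrid",
            components=(parse_component("s_gazetteer"), parse_component("pos")),
            seed=seed,
        ),
        "gazetteer_ner": PipelineConfig(
            method="hybrid",
            components=(parse_component("gazetteer"), parse_component("ner")),
            seed=seed,
        ),
        "s_gazetteer_ner": PipelineConfig(
            method="hybrid",
            components=(parse_component("s_gazetteer"), parse_component("ner")),
            seed=seed,
        ),
    }
    try:
        return table[name]
    except KeyError:
        raise ConfigurationError(f"unknown preset {name!r}") from None


@dataclass
class UserInference:
    """Inferred location set for one user, with per-unit provenance."""

    user_id: str
    locations: frozenset = frozenset()
    provenance: dict = field(default_factory=dict)


def vote(inferences: Sequence[Mapping[str, frozenset]]) -> dict[str, frozenset]:
    """Unanimous intersection over ≥2 per-user location-set maps.

    A user missing from a component map counts as having an empty set.
    """
    if len(inferences) < 2:
        raise ConfigurationError("vote requires at least 2 component inferences")
    users: set[str] = set()
    for m in inferences:
        users |= set(m)
    out = {}
    for uid in users:
        sets = [m.get(uid, frozenset()) for m in inferences]
        agreed = frozenset(sets[0])
        for s in sets[1:]:
            agreed &= frozenset(s)
        out[uid] = agreed
    return out


def _apply_level(units: Iterable[AdminUnit], level_filter: str) -> frozenset:
    if level_filter == "both":
        return frozenset(units)
    return frozenset(u for u in units if u.level == level_filter)


def _run_component(
    comp: ComponentConfig,
    corpus: UserCorpus,
    gaz: Gazetteer,
    cfg: PipelineConfig,
    lexicon: KeywordLexicon,
    hmm: Optional[HmmModel],
    tagger,
) -> list[Mention]:
    if comp.method == "gazetteer":
        mentions = extract_gazetteer(
            corpus,
            gaz,
            mode=cfg.seg_mode,
            level_filter="both",
            base_lexicon=lexicon.all_words(),
        )
    elif comp.method == "pos":
        mentions = extract_pos(
            corpus, tagger or BaselinePosTagger(gaz, lexicon.all_words()), gaz
        )
    else:  # ner
        if hmm is None:
            raise ConfigurationError("NER component requires a trained HMM model")
        mentions = extract_ner(corpus, hmm, gaz)

    mentions = keyword_filter(mentions, corpus, lexicon, comp.constraint)

    if comp.pattern:
        allowed: set[tuple[str, str, AdminUnit]] = set()
        for pm in pattern_filter(corpus, gaz, lexicon):
            for u in pm.units:
                allowed.add((pm.user_id, pm.post_id, u))
        restricted = []
        for m in mentions:
            units = frozenset(
                u for u in m.units if (m.user_id, m.post_id, u) in allowed
            )
            if units:
                restricted.append(
                    Mention(
                        user_id=m.user_id,
                        post_id=m.post_id,
                        start=m.start,
                        end=m.end,
                        surface=m.surface,
                        units=units,
                        source=m.source,
                        modes=m.modes,
                    )
                )
        mentions = restricted
    return mentions


def infer_user_locations(
    corpus: UserCorpus,
    gaz: Gazetteer,
    cfg: PipelineConfig,
    hmm: Optional[HmmModel] = None,
    lexicon: Optional[KeywordLexicon] = None,
    tagger=None,
) -> dict[str, UserInference]:
    """Run the configured extractor(s) and reduce to per-user location sets.

    Every corpus user appears in the result, possibly with an empty set; for
    hybrid configurations each component is filtered independently before
    the unanimous vote.
    """
    if lexicon is None:
        lexicon = KeywordLexicon()
        if cfg.augment_keywords:
            lexicon = lexicon.with_augmented()

    components = cfg.resolved_components()
    per_component: list[dict[str, frozenset]] = []
    contributions: dict[tuple[str, AdminUnit], set[str]] = {}

    for comp in components:
        mentions = _run_component(comp, corpus, gaz, cfg, lexicon, hmm, tagger)
        user_sets: dict[str, set[AdminUnit]] = {uid: set() for uid in corpus.users}
        for m in mentions:
            units = _apply_level(m.units, cfg.level_filter)
            user_sets[m.user_id] |= units
            for u in units:
                label = comp.method if comp.constraint == CONSTRAINT_NONE else (
                    f"{comp.method}+{comp.constraint}"
                )
                contributions.setdefault((m.user_id, u), set()).add(label)
        per_component.append({uid: frozenset(s) for uid, s in user_sets.items()})

    if len(per_component) == 1:
        final = per_component[0]
    else:
        final = vote(per_component)

    out = {}
    for uid in corpus.users:
        locs = final.get(uid, frozenset())
        prov = {
            u: sorted(contributions.get((uid, u), ())) for u in locs
        }
        out[uid] = UserInference(user_id=uid, locations=locs, provenance=prov)
    return out


def aggregate_distribution(
    inferences: Mapping[str, UserInference],
    gaz: Gazetteer,
    level: str,
) -> dict[AdminUnit, int]:
    """Per-unit user counts at city or province level.

    Each user contributes at most once per distinct unit; at province level
    every inferred unit is first mapped through its covering province.
    """
    if level not in (PROVINCE, CITY):
        raise ValueError(f"aggregation level must be province or city, got {level!r}")
    counts: dict[AdminUnit, int] = {}
    for inf in inferences.values():
        if level == CITY:
            units = {u for u in inf.locations if u.level == CITY}
        else:
            units = {gaz.province_of(u) for u in inf.locations}
        for u in units:
            counts[u] = counts.get(u, 0) + 1
    return counts


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def write_predictions(
    inferences: Mapping[str, UserInference], target: Union[str, Path]
) -> None:
    """Predictions as JSONL, one object per user, sorted by user id."""
    with open(Path(target), "w", encoding="utf-8") as fh:
        for uid in sorted(inferences):
            inf = inferences[uid]
            locs = sorted(inf.locations, key=lambda u: (u.level, u.canonical_name))
            fh.write(
                json.dumps(
                    {
                        "user_id": uid,
                        "locations": [
                            {"name": u.canonical_name, "level": u.level} for u in locs
                        ],
                        "provenance": {
                            f"{u.canonical_name}/{u.level}": inf.provenance.get(u, [])
                            for u in locs
                        },
                    },
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )


def read_predictions(
    source: Union[str, Path], gaz: Gazetteer
) -> dict[str, frozenset]:
    """Read a predictions JSONL back into per-user unit sets."""
    out: dict[str, frozenset] = {}
    with open(Path(source), encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            units = {gaz.unit(d["name"], d["level"]) for d in rec["locations"]}
            out[rec["user_id"]] = frozenset(units)
    return out


def write_distribution(
    counts: Mapping[AdminUnit, int], target: Union[str, Path]
) -> None:
    """Distribution as CSV ``unit,level,user_count``, descending by count."""
    rows = sorted(
        counts.items(), key=lambda kv: (-kv[1], kv[0].canonical_name, kv[0].level)
    )
    with open(Path(target), "w", encoding="utf-8") as fh:
        fh.write("unit,level,user_count\n")
        for unit, n in rows:
            fh.write(f"{unit.canonical_name},{unit.level},{n}\n")
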