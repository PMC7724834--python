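"""Seeded synthetic corpora of short dating-community posts.

The generator emulates the statistical structure the inference method
assumes: users mostly reveal their true location(s) using one of seven
short syntax patterns, location statements co-occur with context keywords
at a configurable rate, and posts are contaminated with distractor place
mentions (travel talk about other cities) and non-gazetteer POI strings
(tourist attractions).  True locations per user are known, so every stage
of the pipeline can be evaluated without access to real community data.

All template and filler strings are constructed to survive preprocessing
unchanged (no URLs, punctuation or stop words outside the deliberate
punctuation decorations) and to contain no gazetteer surface as a
substring, so the generated clean text, character offsets and NER tags
stay aligned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .corpus import Post, UserCorpus, write_posts
from .errors import GenerationError
from .evaluate import write_gold
from .gazetteer import CITY, AdminUnit, Gazetteer
from .filters import PATTERN_MODES

# Default per-city sampling weights: a plausible big-city skew over the
# bundled gazetteer (normalized at use).
DEFAULT_CITY_WEIGHTS: dict[str, int] = {
    "北京": 8, "上海": 8, "广州": 6, "深圳": 6, "成都": 6, "重庆": 5,
    "武汉": 5, "杭州": 4, "南京": 4, "西安": 4, "长沙": 4, "郑州": 3,
    "天津": 3, "苏州": 3, "青岛": 3, "沈阳": 3, "哈尔滨": 2, "昆明": 2,
    "南宁": 2, "福州": 2, "厦门": 2, "合肥": 2, "南昌": 2, "贵阳": 2,
    "兰州": 2, "太原": 2, "石家庄": 2, "济南": 2, "大连": 2, "宁波": 2,
    "温州": 1, "桂林": 1, "三亚": 1, "香港": 1, "乌鲁木齐": 1,
}

DEFAULT_MODE_WEIGHTS: dict[str, float] = {
    "former_keyword": 0.35,
    "later_keyword": 0.20,
    "global_keyword": 0.10,
    "individual_location": 0.10,
    "individual_with_punct": 0.10,
    "location_with_modal": 0.10,
    "province_with_city": 0.05,
}

# (prefix, suffix) wrapped around the location, per pattern mode.  The
# province_with_city prefix is the parent province name, built at run time.
MODE_TEMPLATES: dict[str, tuple[tuple[str, str], ...]] = {
    "former_keyword": (("坐标", ""), ("定位", ""), ("我在", "等你"), ("坐标", "找对象")),
    "later_keyword": (("", "人找对象"), ("", "有吗"), ("", "附近走走")),
    "global_keyword": (("同城找伴", ""), ("交友看过", ""), ("", "小哥哥私聊")),
    "individual_location": (("", ""),),
    "individual_with_punct": (("", ""),),
    "location_with_modal": (("", "吗"), ("", "呢"), ("", "啊")),
}

PUNCT_DECORATIONS = ("！！", "。。。", "？？", "～～")

BARE_TEMPLATES = ("刚到{loc}", "{loc}走一圈", "夜逛{loc}")
DISTRACTOR_TEMPLATES = ("不过{loc}旅游不错", "看过{loc}风景照", "记得{loc}景点打卡")
POI_TEMPLATES = ("顺便逛逛{poi}", "{poi}夜景不错")

_BASE_TIME = datetime(2021, 1, 1, tzinfo=timezone.utc)


def default_poi_list() -> tuple[str, ...]:
    ref = resources.files("locinfer.data") / "poi.txt"
    return tuple(ref.read_text(encoding="utf-8").split())


@dataclass(frozen=True)
class SimParams:
    """Study conditions for a synthetic corpus.

    ``posts_per_user`` is an int or an inclusive (lo, hi) range;
    ``location_distribution`` maps city canonical names to probabilities
    (``None`` selects the packaged big-city skew); ``p_keyword`` is the
    probability that a true-location post is realized through one of the
    seven syntax patterns (otherwise the location appears bare);
    ``p_distractor`` and ``p_poi`` are per-post contamination rates.
    """

    n_users: int = 1000
    posts_per_user: Union[int, tuple] = 3
    location_distribution: Optional[Mapping[str, float]] = None
    p_multi_location: float = 0.15
    p_keyword: float = 0.9
    p_distractor: float = 0.3
    p_poi: float = 0.1
    mode_weights: Optional[Mapping[str, float]] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_users < 0:
            raise GenerationError("n_users must be non-negative")
        for name in ("p_multi_location", "p_keyword", "p_distractor", "p_poi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name}={v} outside [0, 1]")
        if self.location_distribution is not None:
            total = sum(self.location_distribution.values())
            if abs(total - 1.0) > 1e-9:
                raise GenerationError(
                    f"location_distribution sums to {total}, not 1"
                )
        if self.mode_weights is not None:
            bad = set(self.mode_weights) - set(PATTERN_MODES)
            if bad:
                raise GenerationError(f"unknown pattern modes: {sorted(bad)}")

    def to_dict(self) -> dict:
        return {
            "n_users": self.n_users,
            "posts_per_user": list(self.posts_per_user)
            if isinstance(self.posts_per_user, tuple)
            else self.posts_per_user,
            "location_distribution": dict(self.location_distribution)
            if self.location_distribution
            else None,
            "p_multi_location": self.p_multi_location,
            "p_keyword": self.p_keyword,
            "p_distractor": self.p_distractor,
            "p_poi": self.p_poi,
            "mode_weights": dict(self.mode_weights) if self.mode_weights else None,
            "seed": self.seed,
        }


def _normalized_distribution(
    params: SimParams, gaz: Gazetteer
) -> tuple[list[str], np.ndarray]:
    if params.location_distribution is not None:
        items = sorted(params.location_distribution.items())
    else:
        items = sorted(
            (name, float(w))
            for name, w in DEFAULT_CITY_WEIGHTS.items()
        )
    names = [name for name, _ in items]
    for name in names:
        units = gaz.canonicalize(name)
        if not any(u.level == CITY for u in units):
            raise GenerationError(
                f"location_distribution entry {name!r} is not a gazetteer city"
            )
    probs = np.array([w for _, w in items], dtype=float)
    probs = probs / probs.sum()
    return names, probs


def _mode_distribution(params: SimParams) -> tuple[list[str], np.ndarray]:
    weights = dict(params.mode_weights or DEFAULT_MODE_WEIGHTS)
    modes = [m for m in PATTERN_MODES if weights.get(m, 0.0) > 0]
    probs = np.array([weights[m] for m in modes], dtype=float)
    if probs.sum() <= 0:
        raise GenerationError("mode_weights must have positive total mass")
    return modes, probs / probs.sum()


def _place_segment(name: str, gaz: Gazetteer) -> tuple[str, frozenset]:
    return name, gaz.canonicalize(name)


def _realize_post(
    rng: np.random.Generator,
    mode: Optional[str],
    loc_name: str,
    gaz: Gazetteer,
    distractor: Optional[str],
    poi: Optional[str],
) -> tuple[list[tuple[str, bool]], str]:
    """Build a post as (text, is_place) segments plus a raw decoration."""
    segments: list[tuple[str, bool]] = []
    decoration = ""
    if mode is None:  # bare location, no pattern / keyword
        template = BARE_TEMPLATES[rng.integers(len(BARE_TEMPLATES))]
        pre, _, post = template.partition("{loc}")
        if pre:
            segments.append((pre, False))
        segments.append((loc_name, True))
        if post:
            segments.append((post, False))
    elif mode == "province_with_city":
        city_units = [u for u in gaz.canonicalize(loc_name) if u.level == CITY]
        parent = gaz.province_of(city_units[0])
        segments.append((parent.canonical_name, True))
        segments.append((loc_name, True))
    else:
        templates = MODE_TEMPLATES[mode]
        prefix, suffix = templates[rng.integers(len(templates))]
        if prefix:
            segments.append((prefix, False))
        segments.append((loc_name, True))
        if suffix:
            segments.append((suffix, False))
        if mode == "individual_with_punct":
            decoration = PUNCT_DECORATIONS[rng.integers(len(PUNCT_DECORATIONS))]
    if distractor is not None:
        template = DISTRACTOR_TEMPLATES[rng.integers(len(DISTRACTOR_TEMPLATES))]
        pre, _, post = template.partition("{loc}")
        segments.append((pre, False))
        segments.append((distractor, True))
        if post:
            segments.append((post, False))
    if poi is not None:
        template = POI_TEMPLATES[rng.integers(len(POI_TEMPLATES))]
        pre, _, post = template.partition("{poi}")
        if pre:
            segments.append((pre, False))
        segments.append((poi, True))  # POIs are place spans for NER labels
        if post:
            segments.append((post, False))
    return segments, decoration


def _tags_for(segments: Sequence[tuple[str, bool]]) -> tuple[str, list[str]]:
    text_parts = []
    tags: list[str] = []
    for text, is_place in segments:
        text_parts.append(text)
        if not is_place:
            tags.extend("O" for _ in text)
        elif len(text) == 1:
            tags.append("S-LOC")
        else:
            tags.extend(["B-LOC"] + ["M-LOC"] * (len(text) - 2) + ["E-LOC"])
    return "".join(text_parts), tags


def generate_corpus(
    params: SimParams, gaz: Gazetteer
) -> tuple[UserCorpus, dict[str, frozenset], list[tuple[str, list[str]]]]:
    """Generate (corpus, gold labels, character-level NER training labels).

    Determinism: each user draws from an independent RNG stream derived
    from the master seed and the user index, so corpora agree on shared
    prefixes when only ``n_users`` changes.
    """
    params.validate()
    if len(gaz) == 0:
        raise GenerationError("gazetteer is empty")
    loc_names, loc_probs = _normalized_distribution(params, gaz)
    modes, mode_probs = _mode_distribution(params)
    pois = default_poi_list()
    all_city_names = sorted(
        u.canonical_name for u in gaz.cities
    )

    corpus = UserCorpus()
    gold: dict[str, frozenset] = {}
    ner_labels: list[tuple[str, list[str]]] = []

    for uidx in range(params.n_users):
        rng = np.random.default_rng([params.seed, uidx])
        uid = f"u{uidx:06d}"

        n_true = 2 if rng.random() < params.p_multi_location else 1
        n_true = min(n_true, len(loc_names))
        drawn = list(
            rng.choice(loc_names, size=n_true, replace=False, p=loc_probs)
        )
        gold_units: set[AdminUnit] = set()
        for name in drawn:
            gold_units |= gaz.canonicalize(name)

        # Pool of distractor cities guaranteed disjoint from anything that
        # could end up in this user's gold set (true units and the parent
        # provinces a province_with_city post may add).
        excluded = set(gold_units)
        for u in list(gold_units):
            excluded.add(gaz.province_of(u))
        distractor_pool = [
            n for n in all_city_names if not (gaz.canonicalize(n) & excluded)
        ]

        if isinstance(params.posts_per_user, tuple):
            lo, hi = params.posts_per_user
            n_posts = int(rng.integers(lo, hi + 1))
        else:
            n_posts = int(params.posts_per_user)
        n_posts = max(n_posts, len(drawn), 1)

        for k in range(n_posts):
            # forced coverage: the first posts state each true location once
            loc_name = (
                drawn[k]
                if k < len(drawn)
                else drawn[int(rng.integers(len(drawn)))]
            )
            if rng.random() < params.p_keyword:
                mode = modes[
                    int(rng.choice(len(modes), p=mode_probs))
                ]
                if mode == "province_with_city":
                    city_units = [
                        u for u in gaz.canonicalize(loc_name) if u.level == CITY
                    ]
                    parent = gaz.province_of(city_units[0])
                    if parent.canonical_name == loc_name:
                        mode = "former_keyword"  # municipality: no distinct parent
                    else:
                        gold_units.add(parent)
            else:
                mode = None
            distractor = None
            if distractor_pool and rng.random() < params.p_distractor:
                distractor = distractor_pool[int(rng.integers(len(distractor_pool)))]
            poi = pois[int(rng.integers(len(pois)))] if rng.random() < params.p_poi else None

            segments, decoration = _realize_post(rng, mode, loc_name, gaz, distractor, poi)
            clean, tags = _tags_for(segments)
            raw = clean + decoration
            stamp = _BASE_TIME + timedelta(minutes=uidx * 100 + k)
            post = Post(
                user_id=uid,
                post_id=f"{uid}-p{k}",
                timestamp=stamp.isoformat(),
                raw_text=raw,
                clean_text=clean,
            )
            corpus.add(post)
            ner_labels.append((clean, tags))

        gold[uid] = frozenset(gold_units)

    return corpus, gold, ner_labels


def write_ner_labels(
    labels: Sequence[tuple[str, Sequence[str]]], target: Union[str, Path]
) -> None:
    with open(Path(target), "w", encoding="utf-8") as fh:
        for text, tags in labels:
            fh.write(
                json.dumps({"text": text, "tags": list(tags)}, ensure_ascii=False)
                + "\n"
            )


def read_ner_labels(source: Union[str, Path]) -> list[tuple[str, list[str]]]:
    out = []
    with open(Path(source), encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            out.append((rec["text"], list(rec["tags"])))
    return out


def write_fixture(
    corpus: UserCorpus,
    gold: Mapping[str, frozenset],
    labels: Sequence[tuple[str, Sequence[str]]],
    directory: Union[str, Path],
    params: Optional[SimParams] = None,
) -> dict[str, Path]:
    """Write corpus.jsonl, gold.jsonl, ner_train.jsonl (and params.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": directory / "corpus.jsonl",
        "gold": directory / "gold.jsonl",
        "ner_train": directory / "ner_train.jsonl",
    }
    write_posts(corpus, paths["corpus"])
    write_gold(gold, paths["gold"])
    write_ner_labels(labels, paths["ner_train"])
    if params is not None:
        paths["params"] = directory / "params.json"
        paths["params"].write_text(
            json.dumps(params.to_dict(), ensure_ascii=False, sort_keys=True, indent=1),
            encoding="utf-8",
        )
    return paths
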