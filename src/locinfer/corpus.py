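"""Post corpora: reading, writing, grouping by user, and text preprocessing.

Preprocessing removes, in order, URLs, punctuation/symbol characters and
stop words.  Stop words are removed as whole segmented tokens (never as raw
substrings) so that place names and context keywords containing a stop-word
character survive intact; callers may pass a ``protect`` dictionary (e.g.
gazetteer surfaces) that segmentation keeps whole.
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Union

from .errors import CorpusParseError
from .segmentation import segment

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)


@dataclass(frozen=True)
class Post:
    user_id: str
    post_id: str
    timestamp: str
    raw_text: str
    clean_text: str

    def __post_init__(self) -> None:
        if not self.user_id or not self.post_id:
            raise CorpusParseError("Post requires non-empty user_id and post_id")


class UserCorpus:
    """Posts grouped by user, preserving per-user input order."""

    def __init__(self, posts: Iterable[Post] = ()):
        self.users: dict[str, list[Post]] = {}
        self._by_key: dict[tuple[str, str], Post] = {}
        for post in posts:
            self.add(post)

    def add(self, post: Post) -> None:
        self.users.setdefault(post.user_id, []).append(post)
        self._by_key[(post.user_id, post.post_id)] = post

    @property
    def n_users(self) -> int:
        return len(self.users)

    @property
    def n_posts(self) -> int:
        return sum(len(v) for v in self.users.values())

    def posts_of(self, user_id: str) -> list[Post]:
        return list(self.users.get(user_id, []))

    def get(self, user_id: str, post_id: str) -> Optional[Post]:
        return self._by_key.get((user_id, post_id))

    def iter_posts(self) -> Iterator[Post]:
        for posts in self.users.values():
            yield from posts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UserCorpus):
            return NotImplemented
        return self.users == other.users

    def __repr__(self) -> str:
        return f"UserCorpus(n_users={self.n_users}, n_posts={self.n_posts})"


def default_stopwords() -> frozenset:
    """The packaged stop-word list.

    Deliberately small: single-character function words that double as
    context keywords (在, 是, 人, 的, ...) and modal particles are excluded,
    because the keyword and pattern filters operate on the cleaned text.
    """
    ref = resources.files("locinfer.data") / "stopwords.txt"
    words = ref.read_text(encoding="utf-8").split()
    return frozenset(words)


def _is_removable_char(ch: str) -> bool:
    # Punctuation (P*), symbols (S*), whitespace/separators and controls.
    cat = unicodedata.category(ch)
    return cat[0] in ("P", "S", "Z", "C")


def strip_punctuation(text: str) -> str:
    return "".join(ch for ch in text if not _is_removable_char(ch))


def preprocess(
    raw_text: str,
    stopwords: Optional[Iterable[str]] = None,
    protect: Iterable[str] = (),
) -> str:
    """Clean a post: drop URLs, then punctuation/symbols, then stop words.

    Stop-word removal segments the text (forward maximum matching over the
    union of the stop-word list and ``protect``) and drops tokens that are
    stop words; the pass is iterated to a fixed point so the operation is
    idempotent.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    stopset = {unicodedata.normalize("NFC", w) for w in stopwords if w}
    text = unicodedata.normalize("NFC", raw_text)
    text = _URL_RE.sub("", text)
    text = strip_punctuation(text)
    if not stopset:
        return text
    dictionary = stopset | {w for w in protect if w}
    for _ in range(10):  # fixed-point iteration; converges in 1-2 passes
        tokens = segment(text, dictionary, mode="accurate")
        cleaned = "".join(t.text for t in tokens if t.text not in stopset)
        if cleaned == text:
            break
        text = cleaned
    return text


def _build_post(
    record: Mapping[str, object],
    lineno: int,
    stopwords: Optional[Iterable[str]],
    protect: Iterable[str],
) -> Post:
    user_id = str(record.get("user_id") or "").strip()
    text = record.get("text")
    if not user_id:
        raise CorpusParseError(f"line {lineno}: missing user_id")
    if text is None or (isinstance(text, float) and text != text):
        raise CorpusParseError(f"line {lineno}: missing text field")
    raw = str(text)
    post_id = str(record.get("post_id") or "").strip() or f"line{lineno}"
    timestamp = str(record.get("timestamp") or "").strip()
    return Post(
        user_id=user_id,
        post_id=post_id,
        timestamp=timestamp,
        raw_text=raw,
        clean_text=preprocess(raw, stopwords=stopwords, protect=protect),
    )


def read_posts(
    source: Union[str, Path],
    stopwords: Optional[Iterable[str]] = None,
    protect: Iterable[str] = (),
) -> UserCorpus:
    """Read a JSONL (default) or CSV corpus and group posts by user.

    Each record needs ``user_id`` and ``text``; ``post_id`` and
    ``timestamp`` are optional.  Malformed records raise
    :class:`CorpusParseError` naming the line number.
    """
    path = Path(source)
    corpus = UserCorpus()
    if path.suffix.lower() in (".csv", ".tsv"):
        delim = "\t" if path.suffix.lower() == ".tsv" else ","
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delim)
            for lineno, row in enumerate(reader, start=2):
                corpus.add(_build_post(row, lineno, stopwords, protect))
    else:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusParseError(f"line {lineno}: invalid JSON: {exc}") from exc
                corpus.add(_build_post(record, lineno, stopwords, protect))
    return corpus


def write_posts(corpus: UserCorpus, target: Union[str, Path]) -> None:
    """Write a corpus as JSONL (keys user_id, post_id, timestamp, text)."""
    path = Path(target)
    with open(path, "w", encoding="utf-8") as fh:
        for post in corpus.iter_posts():
            fh.write(
                json.dumps(
                    {
                        "user_id": post.user_id,
                        "post_id": post.post_id,
                        "timestamp": post.timestamp,
                        "text": post.raw_text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
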