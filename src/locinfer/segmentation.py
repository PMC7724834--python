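"""Dictionary-driven Chinese word segmentation.

Two modes are supported, mirroring the two segmentation strategies used
throughout the pipeline:

* ``accurate`` — forward maximum matching: at every position the longest
  dictionary word is consumed; where no dictionary word starts, the single
  character is emitted.  The resulting tokens partition the text.
* ``full`` — every substring of the text that is a dictionary word is
  emitted, plus every single character (unigram), ordered by position.
  Full mode trades precision for recall: it never misses a dictionary
  word, at the cost of emitting overlapping, ambiguous tokens.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

ACCURATE = "accurate"
FULL = "full"
SEGMENTATION_MODES = (ACCURATE, FULL)


class Token(NamedTuple):
    """A token with 0-based, end-exclusive character offsets."""

    text: str
    start: int
    end: int


def segment(text: str, dictionary: Iterable[str], mode: str = ACCURATE) -> list[Token]:
    """Segment ``text`` against ``dictionary`` in the given mode.

    Parameters
    ----------
    text:
        The input string (typically a preprocessed post).
    dictionary:
        Known words.  Empty entries are ignored.
    mode:
        ``"accurate"`` (forward maximum matching, partitions the text) or
        ``"full"`` (all dictionary substrings plus all unigrams).
    """
    if mode not in SEGMENTATION_MODES:
        raise ValueError(f"unknown segmentation mode: {mode!r}")
    words = {w for w in dictionary if w}
    if not text:
        return []
    if mode == ACCURATE:
        return _forward_maximum_matching(text, words)
    return _full_scan(text, words)


def _forward_maximum_matching(text: str, words: set[str]) -> list[Token]:
    max_len = max((len(w) for w in words), default=1)
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        match_end = i + 1
        for length in range(min(max_len, n - i), 1, -1):
            if text[i : i + length] in words:
                match_end = i + length
                break
        tokens.append(Token(text[i:match_end], i, match_end))
        i = match_end
    return tokens


def _full_scan(text: str, words: set[str]) -> list[Token]:
    n = len(text)
    max_len = max((len(w) for w in words), default=1)
    tokens = [Token(text[i], i, i + 1) for i in range(n)]
    for i in range(n):
        for length in range(2, min(max_len, n - i) + 1):
            cand = text[i : i + length]
            if cand in words:
                tokens.append(Token(cand, i, i + length))
    tokens.sort(key=lambda t: (t.start, t.end))
    return tokens
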