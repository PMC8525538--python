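"""Tokenization, sentence splitting and keyword extraction."""

from __future__ import annotations

import re
from collections import Counter

from ._wordlists import STOPWORDS

__all__ = ["tokenize", "split_sentences", "extract_keywords"]

_HASHTAG_RE = re.compile(r"#[^#]*#?")
_TOKEN_RE = re.compile(r"[a-z0-9]+")
_SENT_SPLIT_RE = re.compile(r"[.!?]+")


def strip_hashtags(text: str) -> str:
    """Remove ``#tag#`` spans; hashtags delimit community membership and are
    not message content."""
    return _HASHTAG_RE.sub(" ", text)


def tokenize(text: str) -> list[str]:
    """Lowercased alphanumeric tokens, hashtags removed.

    Apostrophes split their word ("it's" -> "it", "s"), matching the crude
    token-list approximations used by the readability features.
    """
    return _TOKEN_RE.findall(strip_hashtags(text).lower())


def split_sentences(text: str) -> list[str]:
    """Split on terminal punctuation; empty fragments dropped."""
    parts = _SENT_SPLIT_RE.split(strip_hashtags(text))
    return [p.strip() for p in parts if p.strip()]


def extract_keywords(text: str, k: int = 5, stopwords: frozenset[str] = STOPWORDS) -> list[str]:
    """Top-``k`` content words ranked by in-message term frequency.

    Stopwords and hashtags are removed first.  Ties are broken by first
    occurrence, which makes the extraction deterministic.  Text that is
    empty after cleaning yields an empty list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tokens = [t for t in tokenize(text) if t not in stopwords]
    if not tokens:
        return []
    counts = Counter(tokens)
    first = {}
    for i, t in enumerate(tokens):
        first.setdefault(t, i)
    ranked = sorted(counts, key=lambda t: (-counts[t], first[t]))
    return ranked[:k]
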