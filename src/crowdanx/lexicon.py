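"""Lexicon containers and file formats.

File formats (all UTF-8 text):

* word lists / anchor lexicons: one term per line, optional ``<TAB>weight``;
* frequency lexicons: ``token<TAB>count`` per line, ordered by rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._wordlists import ANXIETY_ANCHORS

__all__ = ["AnchorLexicon", "FrequencyLexicon", "read_lexicon", "write_lexicon",
           "read_frequency_lexicon", "write_frequency_lexicon"]


@dataclass(frozen=True)
class AnchorLexicon:
    """Anxiety anchor keywords with optional per-word weights.

    Terms are normalized to lowercase; weights default to 1.
    """

    words: tuple[str, ...] = ANXIETY_ANCHORS
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.words:
            raise ValueError("anchor lexicon must be non-empty")
        object.__setattr__(self, "words", tuple(w.lower() for w in self.words))
        object.__setattr__(
            self, "weights", {w.lower(): float(x) for w, x in self.weights.items()}
        )

    def weight(self, word: str) -> float:
        return self.weights.get(word, 1.0)


@dataclass(frozen=True)
class FrequencyLexicon:
    """Rank-ordered word counts; "difficult" words are absent from the top N."""

    counts: dict[str, int]

    def top(self, n: int) -> frozenset[str]:
        cache = self.__dict__.setdefault("_top_cache", {})
        if n not in cache:
            cache[n] = frozenset(list(self.counts)[:n])
        return cache[n]

    def frequency(self, token: str) -> int | None:
        return self.counts.get(token)


def read_lexicon(path) -> AnchorLexicon:
    words, weights = [], {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) > 2:
                raise ValueError(f"{path}:{lineno}: expected 'term' or 'term<TAB>weight'")
            words.append(parts[0].strip())
            if len(parts) == 2:
                weights[parts[0].strip()] = float(parts[1])
    return AnchorLexicon(tuple(words), weights)


def write_lexicon(lexicon: AnchorLexicon, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for w in lexicon.words:
            if w in lexicon.weights:
                fh.write(f"{w}\t{lexicon.weights[w]!r}\n")
            else:
                fh.write(f"{w}\n")


def read_frequency_lexicon(path) -> FrequencyLexicon:
    counts: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'token<TAB>count'")
            counts[parts[0]] = int(parts[1])
    return FrequencyLexicon(counts)


def write_frequency_lexicon(lexicon: FrequencyLexicon, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tok, cnt in lexicon.counts.items():
            fh.write(f"{tok}\t{cnt}\n")
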