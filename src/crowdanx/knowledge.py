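"""Declarative-knowledge scoring of messages.

Each message is scored on three criteria and combined linearly:

    DK(m) = a * source_credibility + b * text_similarity + c * text_readability

Source credibility is binary (origin author institution-verified), text
similarity is the cosine between message keywords and the community topic,
and text readability comes from a CRIE-style index

    4.53 + 0.01*dw - 0.86*ssr - 1.45*log_cwf + 0.02*pp

which behaves like a difficulty grade; before entering DK it is z-scored
within the corpus and negated so that higher scaled readability means
easier text (an interpretive choice, flagged in the docs).  Community-level
knowledge at time t is the plain sum over messages present by t.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._wordlists import CLAUSE_MARKERS, PERSONAL_PRONOUNS, STOPWORDS
from .embeddings import WordEmbedding, _cos
from .lexicon import FrequencyLexicon
from .text import extract_keywords, split_sentences, tokenize

__all__ = [
    "ReadabilityFeatures", "readability_raw", "extract_readability_features",
    "scale_readability", "DKWeights", "DKComponents", "dk_message",
    "dk_community", "trace_origin", "label_source_credibility",
    "topic_text_similarity",
]

log = logging.getLogger(__name__)

#: Printed coefficients of the readability index.
READABILITY_INTERCEPT = 4.53
READABILITY_COEFS = {"difficult_words": 0.01, "simple_sentence_ratio": -0.86,
                     "log_content_word_freq": -1.45, "personal_pronouns": 0.02}

DEFAULT_DIFFICULT_TOP_N = 5000


@dataclass(frozen=True)
class ReadabilityFeatures:
    difficult_words: int
    simple_sentence_ratio: float
    log_content_word_freq: float
    personal_pronouns: int

    def __post_init__(self):
        if self.difficult_words < 0 or self.personal_pronouns < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.simple_sentence_ratio <= 1.0:
            raise ValueError("simple_sentence_ratio must be in [0,1]")


def readability_raw(features: ReadabilityFeatures) -> float:
    """The readability index with its printed coefficients, exactly."""
    c = READABILITY_COEFS
    return (READABILITY_INTERCEPT
            + c["difficult_words"] * features.difficult_words
            + c["simple_sentence_ratio"] * features.simple_sentence_ratio
            + c["log_content_word_freq"] * features.log_content_word_freq
            + c["personal_pronouns"] * features.personal_pronouns)


def extract_readability_features(text: str, freq_lexicon: FrequencyLexicon,
                                 pronouns=PERSONAL_PRONOUNS,
                                 markers=CLAUSE_MARKERS,
                                 top_n: int = DEFAULT_DIFFICULT_TOP_N,
                                 stopwords=STOPWORDS) -> ReadabilityFeatures:
    """Token-list approximations of the four readability features.

    * difficult words: tokens absent from the top-``top_n`` entries of the
      frequency lexicon;
    * simple sentence ratio: fraction of sentences containing no
      subordinating/coordinating marker;
    * content word frequency: mean log10 lexicon count of non-stopword
      tokens found in the lexicon;
    * personal pronouns: pronoun-list hits.

    Empty text yields all-zero features (ssr undefined, reported as 0).
    """
    tokens = tokenize(text)
    if not tokens:
        log.debug("empty text after cleaning; readability features zeroed")
        return ReadabilityFeatures(0, 0.0, 0.0, 0)
    common = freq_lexicon.top(top_n)
    pronoun_set = frozenset(pronouns) if not isinstance(pronouns, frozenset) else pronouns
    marker_set = frozenset(markers) if not isinstance(markers, frozenset) else markers
    dw = pp = n_cw = 0
    log_sum = 0.0
    counts = freq_lexicon.counts
    for t in tokens:
        if t not in common:
            dw += 1
        if t in pronoun_set:
            pp += 1
        if t not in stopwords:
            f = counts.get(t)
            if f is not None:
                log_sum += math.log10(f)
                n_cw += 1
    log_cwf = log_sum / n_cw if n_cw else 0.0
    sentences = split_sentences(text)
    if sentences:
        simple = sum(1 for s in sentences
                     if marker_set.isdisjoint(tokenize(s)))
        ssr = simple / len(sentences)
    else:
        ssr = 0.0
    return ReadabilityFeatures(dw, ssr, log_cwf, pp)


def scale_readability(raw) -> np.ndarray:
    """z-score within the corpus and negate, so higher = easier text.

    A constant column (zero variance) scales to all zeros.
    """
    raw = np.asarray(raw, dtype=float)
    sd = raw.std()
    if sd == 0.0:
        return np.zeros_like(raw)
    return -(raw - raw.mean()) / sd


@dataclass(frozen=True)
class DKWeights:
    """Weights of the three DK criteria; non-negative, default equal."""

    a: float = 1.0 / 3.0
    b: float = 1.0 / 3.0
    c: float = 1.0 / 3.0

    def __post_init__(self):
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError("DK weights must be non-negative")


@dataclass(frozen=True)
class DKComponents:
    message_id: object
    source_credibility: int
    text_similarity: float
    text_readability: float          # scaled, higher = more readable
    weights: DKWeights = DKWeights()

    @property
    def dk(self) -> float:
        return dk_message(self.source_credibility, self.text_similarity,
                          self.text_readability, self.weights)


def dk_message(credibility, similarity, readability_scaled,
               weights: DKWeights = DKWeights()):
    """DK(m) = a*credibility + b*similarity + c*scaled readability."""
    out = (weights.a * np.asarray(credibility, dtype=float)
           + weights.b * np.asarray(similarity, dtype=float)
           + weights.c * np.asarray(readability_scaled, dtype=float))
    return float(out) if out.ndim == 0 else out


def dk_community(dk_values) -> float:
    """DK(C, t): sum of DK(m) over the messages present in C at time t."""
    return float(np.sum(np.asarray(dk_values, dtype=float))) if len(dk_values) else 0.0


def trace_origin(message_id, messages: pd.DataFrame):
    """Follow repost/comment parent links to the root post of the chain.

    ``messages`` needs ``id`` and ``parent`` columns (parent NA for
    originals).  A parent outside the dataset resolves to None (origin
    unknown); a cycle is an error naming the cycle.
    """
    parent = dict(zip(messages["id"], messages["parent"]))
    if message_id not in parent:
        raise KeyError(f"unknown message id {message_id!r}")
    seen = [message_id]
    cur = message_id
    while True:
        nxt = parent.get(cur)
        if nxt is None or (isinstance(nxt, float) and np.isnan(nxt)):
            return cur
        if nxt not in parent:
            log.warning("repost chain of %r leaves the dataset at %r", message_id, nxt)
            return None
        if nxt in seen:
            raise ValueError(f"cycle in repost chain: {seen + [nxt]}")
        seen.append(nxt)
        cur = nxt


def label_source_credibility(origin_profile: pd.Series | None) -> int:
    """1 iff the origin's personal account is institution-verified.

    An unresolved origin (profile None) is treated as not credible.
    """
    if origin_profile is None:
        log.warning("origin unresolved; credibility set to 0")
        return 0
    return int(bool(origin_profile["is_verified"]))


def topic_text_similarity(text: str, topic_label: str,
                          embedding: WordEmbedding, k: int = 5) -> float:
    """Cosine between the mean keyword vector and the topic-label vector,
    clamped to [0,1].  No embeddable tokens -> 0 with a warning."""
    if topic_label not in embedding:
        log.warning("topic label %r not covered by the embedding", topic_label)
        return 0.0
    mean_vec = embedding.mean_vector(extract_keywords(text, k=k))
    if mean_vec is None:
        log.warning("message has no embeddable keywords; similarity 0")
        return 0.0
    return float(np.clip(_cos(mean_vec, embedding.vector(topic_label)), 0.0, 1.0))
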