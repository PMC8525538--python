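"""Word-vector backends.

Three interchangeable sources of token vectors are provided, all exposing
the same :class:`WordEmbedding` mapping interface:

* vectors read from a text word2vec file (``read_word2vec``),
* deterministic hashed vectors (``hashed_embedding``), useful when no
  trained vectors are available and only token identity matters,
* hand-built vectors passed directly to :class:`WordEmbedding`, used by the
  test fixtures.
"""

from __future__ import annotations

import hashlib
from collections.abc import Iterable, Mapping

import numpy as np

__all__ = [
    "WordEmbedding",
    "hashed_embedding",
    "hashed_vector",
    "read_word2vec",
    "write_word2vec",
]


class WordEmbedding:
    """A token -> vector mapping with cosine helpers.

    Unknown tokens have no vector; similarity queries skip them.
    """

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise ValueError("embedding must contain at least one vector")
        dims = {np.asarray(v).shape for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector shapes: {sorted(dims)}")
        self._vectors = {t: np.asarray(v, dtype=np.float64) for t, v in vectors.items()}
        self.dim = next(iter(self._vectors.values())).shape[0]

    def __contains__(self, token: str) -> bool:
        return token in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def tokens(self) -> list[str]:
        return list(self._vectors)

    def vector(self, token: str) -> np.ndarray:
        return self._vectors[token]

    def cosine(self, a: str, b: str) -> float:
        """Cosine similarity between two tokens' vectors."""
        va, vb = self._vectors[a], self._vectors[b]
        return _cos(va, vb)

    def mean_vector(self, tokens: Iterable[str]) -> np.ndarray | None:
        """Mean vector of the embeddable tokens, or None if none embed."""
        vs = [self._vectors[t] for t in tokens if t in self._vectors]
        if not vs:
            return None
        return np.mean(vs, axis=0)

    def max_similarity_table(self, targets: Iterable[str],
                             weights: Mapping[str, float] | None = None) -> dict[str, float]:
        """Per-vocabulary-token max (optionally weighted) cosine to ``targets``.

        Cosines are clamped to [0, 1].  Used to precompute anchor
        similarities once per corpus so bulk scoring is a dictionary lookup.
        """
        tgt = [t for t in targets if t in self._vectors]
        if not tgt:
            raise ValueError("no target token is covered by the embedding")
        w = np.array([1.0 if weights is None else weights.get(t, 1.0) for t in tgt])
        mat = np.stack([self._unit(t) for t in tgt])  # (n_targets, dim)
        out: dict[str, float] = {}
        for tok in self._vectors:
            sims = mat @ self._unit(tok)
            out[tok] = float(np.clip(sims * w, 0.0, None).max())
        return out

    def _unit(self, token: str) -> np.ndarray:
        v = self._vectors[token]
        n = np.linalg.norm(v)
        return v / n if n > 0 else v


def _cos(va: np.ndarray, vb: np.ndarray) -> float:
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(va @ vb / (na * nb))


def hashed_vector(token: str, dim: int, seed: int = 0) -> np.ndarray:
    """Deterministic pseudo-random unit-scale vector for ``token``.

    Stable across processes and platforms (keyed on a BLAKE2 digest of the
    token, not on Python's randomized ``hash``).
    """
    digest = hashlib.blake2b(f"{seed}:{token}".encode(), digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def hashed_embedding(tokens: Iterable[str], dim: int = 32, seed: int = 0) -> WordEmbedding:
    return WordEmbedding({t: hashed_vector(t, dim, seed) for t in dict.fromkeys(tokens)})


def read_word2vec(path) -> WordEmbedding:
    """Read a text word2vec file (header ``n dim``, then token + floats)."""
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header!r}")
        n, dim = int(header[0]), int(header[1])
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}:{lineno}: expected {dim} floats")
            vectors[parts[0]] = np.array(parts[1:], dtype=np.float64)
    if len(vectors) != n:
        raise ValueError(f"{path}: header declares {n} vectors, found {len(vectors)}")
    return WordEmbedding(vectors)


def write_word2vec(embedding: WordEmbedding, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(embedding)} {embedding.dim}\n")
        for tok in embedding.tokens():
            vals = " ".join(repr(float(x)) for x in embedding.vector(tok))
            fh.write(f"{tok} {vals}\n")
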