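"""Embedding provider contract and deterministic built-in providers.

Variable harmonization represents each free-text label by the mean of
its word vectors (word stage, used for pair flagging) or by a single
sentence vector (sentence stage, used to validate clusters).  Both
stages are served through one small contract so that real pre-trained
backends (GloVe via gensim, sentence-transformer models) can be plugged
in where available, while tests and offline runs use the deterministic
providers below.

Every provider must be deterministic — the same text always yields the
same vector — and produce vectors of a single stated dimension.
"""

from __future__ import annotations

import hashlib
from abc import ABC, abstractmethod
from typing import Mapping

import numpy as np


class EmbeddingProvider(ABC):
    """Contract: token- and phrase-level vectors of one fixed dimension.

    ``word_vector``/``phrase_vector`` return ``None`` for text the
    provider cannot embed (out of vocabulary), never a zero vector.
    """

    @property
    @abstractmethod
    def dimension(self) -> int: ...

    @abstractmethod
    def word_vector(self, token: str) -> np.ndarray | None: ...

    def phrase_vector(self, text: str) -> np.ndarray | None:
        """Default sentence stage: mean of in-vocabulary word vectors."""
        from .harmonize import normalize_label

        vectors = [self.word_vector(t) for t in normalize_label(text)]
        vectors = [v for v in vectors if v is not None]
        if not vectors:
            return None
        return np.mean(vectors, axis=0)


class HashingEmbeddingProvider(EmbeddingProvider):
    """Deterministic pseudo-random word vectors keyed by token hash.

    Each token maps to a unit Gaussian vector seeded from its BLAKE2
    digest, so distinct tokens get (almost surely) near-orthogonal
    vectors in high dimension.  Useful as a dependency-free default: it
    treats equal tokens as identical and different tokens as unrelated,
    which is exactly the behaviour exact-duplicate detection needs,
    but it carries no semantic similarity between synonyms.
    """

    def __init__(self, dimension: int = 64, salt: str = "cldkit") -> None:
        if dimension <= 0:
            raise ValueError("dimension must be positive")
        self._dimension = dimension
        self._salt = salt

    @property
    def dimension(self) -> int:
        return self._dimension

    @property
    def name(self) -> str:
        return f"hashing-{self._dimension}"

    def word_vector(self, token: str) -> np.ndarray | None:
        if not token:
            return None
        digest = hashlib.blake2b(
            f"{self._salt}:{token}".encode(), digest_size=8
        ).digest()
        seed = int.from_bytes(digest, "big") % (2**32)
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(self._dimension)
        return v / np.linalg.norm(v)


class FixtureEmbeddingProvider(EmbeddingProvider):
    """Table-driven provider for tests and planted-cluster fixtures.

    Backed by an explicit token -> vector mapping (e.g. planted concept
    anchors plus perturbations from the synthetic elicitation
    generator); anything outside the table is out of vocabulary.
    """

    def __init__(self, word_vectors: Mapping[str, np.ndarray], name: str = "fixture") -> None:
        if not word_vectors:
            raise ValueError("fixture provider needs at least one vector")
        dims = {np.asarray(v).shape for v in word_vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"fixture vectors have mixed shapes: {dims}")
        self._table = {t: np.asarray(v, dtype=float) for t, v in word_vectors.items()}
        self._dimension = next(iter(self._table.values())).shape[0]
        self.name = name

    @property
    def dimension(self) -> int:
        return self._dimension

    def word_vector(self, token: str) -> np.ndarray | None:
        return self._table.get(token)
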