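"""Embedding-based chunk retrieval.

The question text is encoded alongside every chunk in the store with a
pluggable sentence encoder; cosine similarity ranks the chunks and the
top (or, for the low-similarity ablation, bottom) ``count`` are
returned.  Production runs plug in a sentence-transformer behind
:class:`Encoder`; the shipped :class:`HashedBowEncoder` is a
deterministic hashed bag-of-words encoder that keeps the whole stage
testable with no model download.
"""

from __future__ import annotations

import hashlib
import logging
import re
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .chunking import Chunk, ChunkStore

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"\w+")


class Encoder(ABC):
    """Sentence encoder contract: texts -> fixed-dimension real vectors.

    Encoding must be deterministic within one backend version: the same
    text always maps to the same vector.
    """

    name: str
    dimension: int

    @abstractmethod
    def encode(self, texts: Sequence[str]) -> np.ndarray:
        """Return an array of shape (len(texts), self.dimension)."""


class HashedBowEncoder(Encoder):
    """Deterministic hashed bag-of-words embedding.

    Tokens (lowercased ``\\w+`` runs) are hashed with BLAKE2b to a bucket
    and a sign; token counts accumulate and the vector is L2-normalized.
    Distinct token multisets almost surely yield distinct profiles, and
    shared vocabulary yields higher cosine similarity — enough structure
    for retrieval logic to be exercised exactly, with zero model weights.
    """

    def __init__(self, dimension: int = 256):
        if dimension < 2:
            raise ValueError("dimension must be >= 2")
        self.dimension = dimension
        self.name = f"hashed-bow-{dimension}"

    def _token_slot(self, token: str) -> tuple[int, float]:
        h = int.from_bytes(hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest(), "big")
        return h % self.dimension, 1.0 if (h >> 32) & 1 else -1.0

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dimension), dtype=np.float64)
        for i, text in enumerate(texts):
            tokens = _TOKEN_RE.findall(text.lower())
            if not tokens:
                raise ValueError(f"text {i} has no tokens to encode: {text!r}")
            for tok in tokens:
                idx, sign = self._token_slot(tok)
                out[i, idx] += sign
            norm = np.linalg.norm(out[i])
            if norm == 0.0:  # pathological sign cancellation
                out[i, 0] = 1.0
            else:
                out[i] /= norm
        return out


class EncoderCache(Encoder):
    """In-process memoization wrapper keyed by (backend name, normalized text)."""

    def __init__(self, inner: Encoder):
        self.inner = inner
        self.name = inner.name
        self.dimension = inner.dimension
        self._cache: dict[str, np.ndarray] = {}

    def encode(self, texts: Sequence[str]) -> np.ndarray:
        keys = [" ".join(t.split()) for t in texts]
        missing = [(i, t) for i, (k, t) in enumerate(zip(keys, texts)) if k not in self._cache]
        if missing:
            fresh = self.inner.encode([t for _, t in missing])
            for (i, _), vec in zip(missing, fresh):
                self._cache[keys[i]] = vec
        return np.stack([self._cache[k] for k in keys])


def encode_texts(texts: Sequence[str], encoder: Encoder) -> np.ndarray:
    """Encode texts, checking the contract's declared dimension."""
    if not texts:
        raise ValueError("no texts to encode")
    try:
        vectors = encoder.encode(texts)
    except ValueError:
        raise
    except Exception as exc:  # pragma: no cover - live backend failures
        raise RuntimeError(f"encoder backend {encoder.name!r} failed: {exc}") from exc
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.shape != (len(texts), encoder.dimension):
        raise RuntimeError(
            f"encoder {encoder.name!r} returned shape {vectors.shape}, "
            f"expected {(len(texts), encoder.dimension)}"
        )
    return vectors


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); errors on zero vectors, clipped to [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


@dataclass(frozen=True)
class RetrievalResult:
    chunk: Chunk
    similarity: float
    query: str

    def __post_init__(self) -> None:
        if not -1.0 <= self.similarity <= 1.0:
            raise ValueError(f"similarity {self.similarity} out of [-1, 1]")


def select_relevant_chunks(
    question_text: str,
    store: ChunkStore,
    encoder: Encoder,
    mode: Literal["top", "bottom"] = "top",
    count: int = 1,
) -> list[RetrievalResult]:
    """The ``count`` most (or least) question-similar chunks.

    mode="top" returns descending similarity, mode="bottom" ascending;
    ties break toward the smaller chunk id.  count=0 is the no-knowledge
    ablation and returns an empty list; count beyond the store size
    returns every chunk with a warning.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if len(store) == 0:
        raise ValueError("chunk store is empty")
    if count == 0:
        return []
    if count > len(store):
        logger.warning("requested %d chunks but store holds %d; returning all", count, len(store))
        count = len(store)

    vectors = encode_texts([question_text, *store.texts()], encoder)
    q, chunk_vecs = vectors[0], vectors[1:]
    sims = [cosine_similarity(q, cv) for cv in chunk_vecs]

    if mode == "top":
        order = sorted(range(len(store)), key=lambda i: (-sims[i], store.chunks[i].chunk_id))
    elif mode == "bottom":
        order = sorted(range(len(store)), key=lambda i: (sims[i], store.chunks[i].chunk_id))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return [
        RetrievalResult(chunk=store.chunks[i], similarity=sims[i], query=question_text)
        for i in order[:count]
    ]
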