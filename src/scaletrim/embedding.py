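"""Sentence embeddings for scale items.

One fixed-dimension real vector per item wording. Two backends:

* :class:`FallbackBackend` — a deterministic, offline hashed character
  n-gram encoder (n in {3, 4}) with a fixed random projection. It needs no
  model download, is bit-stable across runs and platforms, and preserves the
  property that texts sharing many n-grams have higher cosine similarity
  than unrelated texts. All tests run on it.
* :class:`TransformerBackend` — a thin adapter over ``sentence-transformers``
  (or any callable mapping texts to vectors), producing e.g. 768-wide BERT
  embeddings when the optional dependency and model weights are available.

Reverse-worded items are embedded via their straightforward rephrasing
(``text_rephrased``); embedding a reverse item without one fails loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import BackendError, SchemaError, ValidationError
from .item_bank import ItemBank

__all__ = [
    "EmbeddingMatrix",
    "FallbackBackend",
    "TransformerBackend",
    "embed_items",
    "fallback_embed",
    "read_embeddings",
    "write_embeddings",
]

_N_BUCKETS = 1 << 16  # hashed n-gram vocabulary size


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Items x d real matrix with row labels and backend provenance."""

    vectors: np.ndarray
    item_ids: tuple[str, ...]
    backend_tag: str

    def __post_init__(self) -> None:
        vec = np.asarray(self.vectors, dtype=float)
        if vec.ndim != 2:
            raise ValidationError("embedding vectors must form a 2-D matrix")
        if vec.shape[0] != len(self.item_ids):
            raise ValidationError("row count does not match item_ids")
        if not np.all(np.isfinite(vec)):
            raise ValidationError("embedding matrix contains non-finite entries")
        norms = np.linalg.norm(vec, axis=1)
        if np.any(norms == 0):
            bad = [self.item_ids[i] for i in np.flatnonzero(norms == 0)]
            raise ValidationError(f"all-zero embedding row(s) for item(s): {bad}")
        object.__setattr__(self, "vectors", vec)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, item_id: str) -> np.ndarray:
        try:
            i = self.item_ids.index(item_id)
        except ValueError:
            raise SchemaError(f"unknown item_id {item_id!r}") from None
        return self.vectors[i]

    def subset(self, item_ids: Sequence[str]) -> "EmbeddingMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return EmbeddingMatrix(self.vectors[idx], tuple(item_ids), self.backend_tag)


def _stable_seed(*parts: str) -> int:
    h = hashlib.blake2b("|".join(parts).encode("utf-8"), digest_size=4)
    return int.from_bytes(h.digest(), "big")


def _ngram_counts(text: str, seed_salt: str) -> dict[int, float]:
    """Signed hashed counts of character 3- and 4-grams.

    Signed hashing keeps collisions unbiased; the bucket space is shared by
    all texts so disjoint n-gram sets occupy (near-)disjoint buckets.
    """
    counts: dict[int, float] = {}
    for n in (3, 4):
        padded = f"#{text}#"
        for i in range(max(len(padded) - n + 1, 0)):
            gram = padded[i : i + n]
            h = hashlib.blake2b(
                f"{seed_salt}|{n}|{gram}".encode("utf-8"), digest_size=5
            ).digest()
            bucket = int.from_bytes(h[:4], "big") % _N_BUCKETS
            sign = 1.0 if h[4] & 1 else -1.0
            counts[bucket] = counts.get(bucket, 0.0) + sign
    return counts


def _projection_row(bucket: int, d: int, seed_salt: str) -> np.ndarray:
    rng = np.random.Generator(
        np.random.PCG64(_stable_seed(seed_salt, "proj", str(bucket), str(d)))
    )
    return rng.standard_normal(d)


def fallback_embed(text: str, d: int = 64, seed_salt: str = "scaletrim") -> np.ndarray:
    """Deterministic offline embedding of a single text.

    Hashed character n-gram counts (n in {3,4}) are projected to ``d``
    dimensions by a fixed Gaussian projection keyed on (bucket, d, salt),
    then length-normalized. Identical texts give identical vectors; texts
    with disjoint n-grams are orthogonal in the bucket space and therefore
    near-orthogonal after projection.
    """
    if not text or not text.strip():
        raise ValidationError("cannot embed empty text")
    if d < 8:
        raise ValidationError("embedding dimension must be >= 8")
    counts = _ngram_counts(text, seed_salt)
    vec = np.zeros(d)
    for bucket, cnt in counts.items():
        vec += cnt * _projection_row(bucket, d, seed_salt)
    norm = np.linalg.norm(vec)
    if norm == 0:  # pragma: no cover - only hash-collision cancellation
        raise ValidationError(f"degenerate zero embedding for text {text!r}")
    return vec / norm


class Backend(Protocol):
    """Anything that maps a list of texts to an items x d matrix."""

    tag: str

    def __call__(self, texts: Sequence[str]) -> np.ndarray: ...


class FallbackBackend:
    """Offline deterministic backend built on :func:`fallback_embed`."""

    def __init__(self, d: int = 64, seed_salt: str = "scaletrim") -> None:
        if d < 8:
            raise ValidationError("embedding dimension must be >= 8")
        self.d = d
        self.seed_salt = seed_salt
        self.tag = f"fallback-ngram(d={d}, salt={seed_salt!r})"

    def __call__(self, texts: Sequence[str]) -> np.ndarray:
        return np.stack([fallback_embed(t, self.d, self.seed_salt) for t in texts])


class TransformerBackend:
    """Mean-pooled transformer sentence encoder (optional dependency).

    Requires ``sentence-transformers`` plus downloaded model weights; when
    those are unavailable the constructor raises a :class:`BackendError`
    telling the caller to use the offline fallback instead.
    """

    def __init__(self, model_name: str = "bert-base-uncased") -> None:
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:
            raise BackendError(
                "sentence-transformers is not installed; use the offline "
                "FallbackBackend (deterministic hashed n-gram embeddings) instead"
            ) from exc
        try:
            self._model = SentenceTransformer(model_name)
        except Exception as exc:  # no network / missing weights
            raise BackendError(
                f"could not load transformer model {model_name!r} "
                "(offline?); use the FallbackBackend instead"
            ) from exc
        self.tag = f"transformer({model_name}, mean-pooling)"

    def __call__(self, texts: Sequence[str]) -> np.ndarray:
        return np.asarray(self._model.encode(list(texts)), dtype=float)


def embed_items(bank: ItemBank, backend: Backend | Callable) -> EmbeddingMatrix:
    """Embed every item of the bank, one row per item in bank order.

    Reverse items are embedded via their rephrased wording; a reverse item
    without ``text_rephrased`` raises before any backend call.
    """
    texts = [it.embedding_text() for it in bank.items]
    vectors = np.asarray(backend(texts), dtype=float)
    tag = getattr(backend, "tag", repr(backend))
    return EmbeddingMatrix(vectors, tuple(bank.item_ids), tag)


def write_embeddings(emb: EmbeddingMatrix, path: str | Path) -> None:
    """CSV of item_id + d numeric columns, with a sidecar JSON of provenance."""
    path = Path(path)
    df = pd.DataFrame(emb.vectors, columns=[f"v{i}" for i in range(emb.dim)])
    df.insert(0, "item_id", list(emb.item_ids))
    df.to_csv(path, index=False, lineterminator="\n")
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps({"backend_tag": emb.backend_tag, "dim": emb.dim}) + "\n",
        encoding="utf-8",
    )


def read_embeddings(path: str | Path) -> EmbeddingMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    if "item_id" not in df.columns:
        raise SchemaError(f"{path}: missing item_id column")
    meta = path.with_suffix(path.suffix + ".meta.json")
    tag = "unknown"
    if meta.exists():
        tag = json.loads(meta.read_text(encoding="utf-8")).get("backend_tag", "unknown")
    ids = tuple(str(i) for i in df["item_id"])
    return EmbeddingMatrix(df.drop(columns="item_id").to_numpy(float), ids, tag)
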