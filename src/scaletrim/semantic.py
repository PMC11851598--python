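"""Semantic similarity indices and semantic item selection.

The semantic route to scale abbreviation needs no response data: items are
embedded, pairwise cosine similarities are computed, each item receives a
*semantic similarity index* — its mean cosine similarity with the other
items of the same subscale — and the k items with the *lowest* indices (the
most semantically unique) form the short form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .embedding import EmbeddingMatrix
from .errors import ParameterError, UndefinedStatisticError, ValidationError
from .item_bank import ItemBank

__all__ = [
    "SimilarityResult",
    "SelectionResult",
    "cosine_similarity",
    "similarity_matrix",
    "semantic_similarity_indices",
    "select_semantic",
]


@dataclass(frozen=True)
class SimilarityResult:
    """Symmetric cosine-similarity matrix with row labels."""

    matrix: np.ndarray
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.item_ids):
            raise ValidationError("similarity matrix shape mismatch")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("similarity matrix not symmetric within 1e-12")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))


@dataclass(frozen=True)
class SelectionResult:
    """A short form: per-subscale ordered item choices plus diagnostics."""

    method: str
    selected: Mapping[str, tuple[str, ...]]
    diagnostics: Mapping[str, object] = field(default_factory=dict)
    seed: int | None = None

    def all_items(self) -> list[str]:
        out: list[str] = []
        for ids in self.selected.values():
            out.extend(ids)
        return out


def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """Dot product over the product of Euclidean norms; in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValidationError("cosine similarity needs two equal-length vectors")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedStatisticError("cosine similarity undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def similarity_matrix(emb: EmbeddingMatrix) -> SimilarityResult:
    """All pairwise cosine similarities; symmetric with unit diagonal."""
    norms = np.linalg.norm(emb.vectors, axis=1)
    # EmbeddingMatrix forbids zero rows, but guard anyway with the item named
    if np.any(norms == 0):  # pragma: no cover
        bad = emb.item_ids[int(np.argmin(norms))]
        raise UndefinedStatisticError(f"zero embedding vector for item {bad!r}")
    unit = emb.vectors / norms[:, None]
    sim = unit @ unit.T
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityResult(sim, emb.item_ids)


def semantic_similarity_indices(
    sim: SimilarityResult, bank: ItemBank, scope: str = "subscale"
) -> pd.Series:
    """Mean cosine similarity of each item with the other items of its group.

    ``scope='subscale'`` (default) averages within the item's subscale only;
    ``scope='scale'`` averages across the whole instrument. Lower index means
    more semantically unique.
    """
    if scope not in ("subscale", "scale"):
        raise ParameterError(f"unknown index scope {scope!r}")
    order = {iid: i for i, iid in enumerate(sim.item_ids)}
    missing = [it.item_id for it in bank.items if it.item_id not in order]
    if missing:
        raise ValidationError(f"similarity matrix lacks item(s): {missing}")

    out = {}
    for it in bank.items:
        i = order[it.item_id]
        if scope == "subscale":
            peers = [order[p.item_id] for p in bank.items_in(it.subscale)
                     if p.item_id != it.item_id]
        else:
            peers = [order[p.item_id] for p in bank.items if p.item_id != it.item_id]
        if not peers:
            raise UndefinedStatisticError(
                f"semantic index undefined: subscale {it.subscale!r} has a single item"
            )
        out[it.item_id] = float(np.mean(sim.matrix[i, peers]))
    return pd.Series(out, name="semantic_similarity_index")


def select_semantic(
    indices: pd.Series, bank: ItemBank, k: int
) -> SelectionResult:
    """Keep, per subscale, the k items with the smallest similarity index.

    Ties break by bank order (the earlier item wins). Selection uses full
    precision; indices are never rounded before ranking.
    """
    selected: dict[str, tuple[str, ...]] = {}
    for sub in bank.subscales:
        members = [it.item_id for it in bank.items_in(sub)]
        if k > len(members):
            raise ParameterError(
                f"k={k} exceeds subscale {sub!r} size {len(members)}"
            )
        vals = []
        for pos, iid in enumerate(members):
            if iid not in indices:
                raise ValidationError(f"no semantic index for item {iid!r}")
            vals.append((float(indices[iid]), pos, iid))
        vals.sort(key=lambda t: (t[0], t[1]))  # stable: bank order breaks ties
        selected[sub] = tuple(iid for _, _, iid in vals[:k])
    return SelectionResult(
        method="semantic",
        selected=selected,
        diagnostics={"indices": indices.to_dict()},
    )
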