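"""Item bank and ordinal response data model.

An :class:`ItemBank` holds the instrument definition: items with subscale
membership, wording, and reverse-scoring flags. A :class:`ResponseMatrix`
holds persons x items ordinal responses coded 1..K with missing values
allowed. Item order in the bank is stable and defines the column order of
every downstream matrix (similarities, parameters, polychorics).

Reverse scoring (x -> K+1-x) is explicit and tracked with a ``scored`` flag:
the IRT/CFA pipeline consumes reverse-scored data, while the embedding
pipeline consumes the rephrased wording of reverse items instead. Conflating
the two silently would corrupt one pipeline or the other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import RangeError, SchemaError, StateError, ValidationError

__all__ = [
    "Item",
    "ItemBank",
    "ResponseMatrix",
    "read_item_bank",
    "write_item_bank",
    "read_responses",
    "write_responses",
    "reverse_score",
]


@dataclass(frozen=True)
class Item:
    """One scale item.

    ``text_rephrased`` is the straightforward rewording of a reverse-worded
    item; it is what gets embedded when ``reverse`` is true.
    """

    item_id: str
    subscale: str
    text: str
    reverse: bool = False
    text_rephrased: str | None = None

    def __post_init__(self) -> None:
        if not str(self.item_id):
            raise ValidationError("item_id must be a non-empty string")
        if not str(self.text).strip():
            raise ValidationError(f"item {self.item_id!r}: text must be non-empty")

    def embedding_text(self) -> str:
        """Wording used for semantic analysis: the rephrased form for reverse items."""
        if self.reverse:
            if not self.text_rephrased or not self.text_rephrased.strip():
                raise ValidationError(
                    f"reverse item {self.item_id!r} has no text_rephrased; "
                    "embedding a reverse-worded item without its straightforward "
                    "rewording is not allowed"
                )
            return self.text_rephrased
        return self.text


@dataclass(frozen=True)
class ItemBank:
    """Ordered collection of items plus the Likert width K."""

    items: tuple[Item, ...]
    n_categories: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if self.n_categories < 2:
            raise ValidationError("n_categories must be >= 2")
        ids = [it.item_id for it in self.items]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate item_id(s): {', '.join(dupes)}")
        if not self.items:
            raise ValidationError("item bank must contain at least one item")

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def subscales(self) -> list[str]:
        """Subscale labels in order of first appearance."""
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.subscale, None)
        return list(seen)

    def items_in(self, subscale: str) -> list[Item]:
        out = [it for it in self.items if it.subscale == subscale]
        if not out:
            raise SchemaError(f"unknown subscale {subscale!r}")
        return out

    def subscale_of(self) -> dict[str, str]:
        return {it.item_id: it.subscale for it in self.items}

    def get(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise SchemaError(f"unknown item_id {item_id!r}")

    def subset(self, item_ids: Sequence[str]) -> "ItemBank":
        """Bank restricted to ``item_ids``, keeping bank order."""
        keep = set(item_ids)
        unknown = keep - set(self.item_ids)
        if unknown:
            raise SchemaError(f"unknown item_id(s): {sorted(unknown)}")
        return ItemBank(
            tuple(it for it in self.items if it.item_id in keep), self.n_categories
        )

    @property
    def reverse_flags(self) -> np.ndarray:
        return np.array([it.reverse for it in self.items], dtype=bool)


@dataclass(frozen=True)
class ResponseMatrix:
    """Persons x items ordinal responses.

    ``values`` is a float array with entries in {1..K} or NaN for missing.
    ``scored`` records whether reverse scoring has been applied.
    """

    values: np.ndarray
    item_ids: tuple[str, ...]
    scored: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValidationError("response values must be a 2-D array")
        if vals.shape[1] != len(self.item_ids):
            raise ValidationError(
                f"{vals.shape[1]} columns but {len(self.item_ids)} item_ids"
            )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def column(self, item_id: str) -> np.ndarray:
        try:
            j = self.item_ids.index(item_id)
        except ValueError:
            raise SchemaError(f"unknown item_id {item_id!r}") from None
        return self.values[:, j]

    def subset(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = []
        for iid in item_ids:
            try:
                idx.append(self.item_ids.index(iid))
            except ValueError:
                raise SchemaError(f"unknown item_id {iid!r}") from None
        return ResponseMatrix(self.values[:, idx], tuple(item_ids), self.scored)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.item_ids))


_BANK_COLUMNS = ["item_id", "subscale", "text", "reverse"]
_TRUE_TOKENS = {"true", "1", "yes", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f", ""}


def _parse_bool(value, where: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise ValidationError(f"{where}: cannot parse boolean from {value!r}")


def read_item_bank(
    path: str | Path, format: str | None = None, n_categories: int = 5
) -> ItemBank:
    """Read an item bank from CSV or JSON.

    CSV columns / JSON object keys: item_id, subscale, text, reverse, and
    optionally text_rephrased. Row order is preserved.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        records = df.to_dict("records")
        have = set(df.columns)
    elif fmt == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(records, list):
            raise SchemaError(f"{path}: JSON item bank must be a list of objects")
        have = set().union(*(r.keys() for r in records)) if records else set()
    else:
        raise SchemaError(f"unknown item bank format {fmt!r}")

    missing = [c for c in _BANK_COLUMNS if c not in have]
    if missing:
        raise SchemaError(f"{path}: missing required field(s): {', '.join(missing)}")

    items = []
    for i, rec in enumerate(records):
        for col in _BANK_COLUMNS:
            if col not in rec:
                raise SchemaError(f"{path} row {i + 1}: missing field {col!r}")
        rephr = rec.get("text_rephrased")
        if rephr is not None and str(rephr).strip() == "":
            rephr = None
        items.append(
            Item(
                item_id=str(rec["item_id"]),
                subscale=str(rec["subscale"]),
                text=str(rec["text"]),
                reverse=_parse_bool(rec["reverse"], f"{path} row {i + 1} 'reverse'"),
                text_rephrased=None if rephr is None else str(rephr),
            )
        )
    return ItemBank(tuple(items), n_categories=n_categories)


def write_item_bank(bank: ItemBank, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = [
        {
            "item_id": it.item_id,
            "subscale": it.subscale,
            "text": it.text,
            "reverse": it.reverse,
            "text_rephrased": it.text_rephrased or "",
        }
        for it in bank.items
    ]
    if fmt == "csv":
        pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
    elif fmt == "json":
        path.write_text(
            json.dumps(rows, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
        )
    else:
        raise SchemaError(f"unknown item bank format {fmt!r}")


def read_responses(
    path: str | Path, bank: ItemBank, missing_token: str = "NA"
) -> ResponseMatrix:
    """Read a persons x items response CSV and align columns to bank order.

    Cells must be integers in 1..K or the missing token.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in set(bank.item_ids)]
    if unknown:
        raise SchemaError(f"{path}: unknown item column(s): {', '.join(unknown)}")
    cols = [iid for iid in bank.item_ids if iid in df.columns]
    df = df[cols]

    K = bank.n_categories
    vals = np.full(df.shape, np.nan)
    raw = df.to_numpy()
    for j, col in enumerate(cols):
        for i in range(raw.shape[0]):
            cell = raw[i, j].strip()
            if cell == missing_token or cell == "":
                continue
            try:
                x = float(cell)
            except ValueError:
                raise RangeError(
                    f"{path}: non-numeric value {cell!r} at (row {i + 1}, col {col})"
                ) from None
            if x != int(x) or not (1 <= x <= K):
                raise RangeError(
                    f"{path}: value {cell} outside 1..{K} at (row {i + 1}, col {col})"
                )
            vals[i, j] = x
    return ResponseMatrix(vals, tuple(cols))


def write_responses(
    responses: ResponseMatrix, path: str | Path, missing_token: str = "NA"
) -> None:
    df = responses.to_frame()
    out = df.map(lambda v: missing_token if np.isnan(v) else str(int(v)))
    out.to_csv(path, index=False, lineterminator="\n")


def reverse_score(responses: ResponseMatrix, bank: ItemBank) -> ResponseMatrix:
    """Recode each reverse item's response x to K+1-x. Apply exactly once.

    The returned matrix carries ``scored=True``; calling again on it raises.
    """
    if responses.scored:
        raise StateError("responses already reverse-scored; refusing to apply twice")
    K = bank.n_categories
    vals = responses.values.copy()
    with np.errstate(invalid="ignore"):
        bad = (vals < 1) | (vals > K)
    if np.any(bad & ~np.isnan(vals)):
        i, j = np.argwhere(bad & ~np.isnan(vals))[0]
        raise RangeError(
            f"value {vals[i, j]} outside 1..{K} at (row {i + 1}, col {responses.item_ids[j]})"
        )
    rev = {it.item_id for it in bank.items if it.reverse}
    for j, iid in enumerate(responses.item_ids):
        if iid in rev:
            vals[:, j] = (K + 1) - vals[:, j]
    return ResponseMatrix(vals, responses.item_ids, scored=True)
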