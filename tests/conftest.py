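"""Shared fixtures: small deterministic banks, response pools, helpers.

All data are generated programmatically; nothing is read from disk except
round-trip temporaries.
"""

from __future__ import annotations

import numpy as np
import pytest

from scaletrim import Item, ItemBank, ResponseMatrix


@pytest.fixture
def tiny_bank() -> ItemBank:
    return ItemBank(
        (
            Item("q1", "anxiety", "I worry my partner will leave me"),
            Item("q2", "anxiety", "I fear being abandoned"),
            Item("q3", "anxiety", "I need frequent reassurance"),
            Item(
                "q4",
                "avoidance",
                "I am very comfortable being close to partners",
                reverse=True,
                text_rephrased="I am not very comfortable being close to partners",
            ),
            Item("q5", "avoidance", "I prefer not to show my feelings"),
            Item("q6", "avoidance", "I pull away when partners get too close"),
        ),
        n_categories=5,
    )


def make_graded_pool(
    loadings, n: int, seed: int, subscale: str = "f", cuts=(-1.0, -0.3, 0.5, 1.1)
) -> tuple[ResponseMatrix, ItemBank]:
    """Single-factor ordinal pool: item j discretizes lam_j * F + noise."""
    rng = np.random.default_rng(seed)
    factor = rng.standard_normal(n)
    cols, ids = [], []
    for j, lam in enumerate(loadings):
        y = lam * factor + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        cols.append(np.digitize(y, list(cuts)) + 1.0)
        ids.append(f"q{j + 1}")
    resp = ResponseMatrix(np.column_stack(cols), tuple(ids), scored=True)
    bank = ItemBank(
        tuple(Item(i, subscale, f"wording {i}") for i in ids), n_categories=5
    )
    return resp, bank


@pytest.fixture
def graded_pool8():
    """8-item pool with graded loadings 0.8..0.35; optimum subset = q1..q4."""
    return make_graded_pool([0.8, 0.75, 0.7, 0.65, 0.5, 0.45, 0.4, 0.35], 2000, 11)


@pytest.fixture
def planted_pool18():
    """18-item pool: 4 strong items (loading 0.8) among 14 weak (0.3)."""
    return make_graded_pool([0.8] * 4 + [0.3] * 14, 2000, 13)
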