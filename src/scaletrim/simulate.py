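"""Synthetic data generators for the full toolkit.

Three generators cover everything the analyses consume:

* :func:`simulate_grm_responses` — ordinal responses from a graded response
  model with two (or more) correlated latent traits, one per subscale;
  returns the true per-person traits so recovery can be checked.
* :func:`generate_clustered_embeddings` — embedding sets with planted
  redundancy clusters: shared-direction construction gives controllable
  within- and between-cluster mean cosine similarity, plus optional
  semantically unique extra items.
* :func:`generate_coupled_fixture` — a joint item-bank/response/embedding
  fixture in which the rank correlation between true item discrimination and
  the semantic similarity index is planted at a chosen value, so the
  discrimination-vs-uniqueness analysis can be validated end to end.

Every generator is seed-deterministic and self-checks its realized
similarity/correlation structure against the requested targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .embedding import EmbeddingMatrix
from .errors import ParameterError, ValidationError
from .grm import GRMItemParams, _category_probs
from .item_bank import Item, ItemBank, ResponseMatrix

__all__ = [
    "SimulationDesign",
    "default_design",
    "simulate_grm_responses",
    "generate_clustered_embeddings",
    "generate_coupled_fixture",
]


@dataclass(frozen=True)
class SimulationDesign:
    """True item parameters per subscale plus the latent-trait correlation."""

    n_persons: int
    items: Mapping[str, tuple[GRMItemParams, ...]]  # subscale -> true params
    factor_corr: float = 0.4
    K: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.factor_corr) >= 1:
            raise ValidationError("|factor_corr| must be < 1")
        if self.n_persons < 1:
            raise ValidationError("n_persons must be positive")
        for sub, params in self.items.items():
            for p in params:
                if p.n_categories != self.K:
                    raise ValidationError(
                        f"subscale {sub!r}: item implies K={p.n_categories}, "
                        f"design says K={self.K}"
                    )

    def bank(self) -> ItemBank:
        """Matching item bank with placeholder wordings (synthetic texts)."""
        items = []
        for sub, params in self.items.items():
            for i in range(len(params)):
                iid = f"{sub}_{i + 1:02d}"
                items.append(
                    Item(iid, sub, f"synthetic item {iid} (placeholder wording)")
                )
        return ItemBank(tuple(items), n_categories=self.K)


def _spread_thresholds(rng, K: int) -> np.ndarray:
    """K-1 ordered thresholds spread over roughly [-2.5, 2.5]."""
    anchors = np.linspace(-2.0, 2.0, K - 1)
    b = np.sort(anchors + rng.uniform(-0.5, 0.5, size=K - 1))
    for i in range(1, len(b)):
        b[i] = max(b[i], b[i - 1] + 0.1)
    return b


def default_design(
    n_persons: int = 2000, seed: int = 0, n_items: int = 18, K: int = 5
) -> SimulationDesign:
    """Two-subscale design at the instrument's operating point.

    Discriminations are drawn uniformly from ranges matching a well-measured
    attachment-style questionnaire (anxiety 1.15-2.24, avoidance 1.55-2.58);
    thresholds spread over about [-2.5, 2.5]; latent traits correlate 0.4.
    """
    rng = np.random.Generator(np.random.PCG64([seed, 90210]))
    items: dict[str, tuple[GRMItemParams, ...]] = {}
    for sub, (a_lo, a_hi) in (("anxiety", (1.15, 2.24)), ("avoidance", (1.55, 2.58))):
        params = tuple(
            GRMItemParams(rng.uniform(a_lo, a_hi), _spread_thresholds(rng, K))
            for _ in range(n_items)
        )
        items[sub] = params
    return SimulationDesign(n_persons, items, factor_corr=0.4, K=K, seed=seed)


def simulate_grm_responses(
    design: SimulationDesign,
) -> tuple[ResponseMatrix, dict[str, np.ndarray]]:
    """Draw ordinal responses from the design's graded response model.

    Latent traits are multivariate normal (unit variances, common pairwise
    correlation ``factor_corr``); each response is drawn from the item's
    category distribution at the person's subscale trait. Returns the
    response matrix (bank column order) and the true traits per subscale.
    """
    subs = list(design.items)
    nf = len(subs)
    rng = np.random.Generator(np.random.PCG64([design.seed, 1]))
    cov = np.full((nf, nf), design.factor_corr)
    np.fill_diagonal(cov, 1.0)
    thetas = rng.multivariate_normal(np.zeros(nf), cov, size=design.n_persons)

    cols: list[np.ndarray] = []
    ids: list[str] = []
    for si, sub in enumerate(subs):
        th = thetas[:, si]
        for i, p in enumerate(design.items[sub]):
            probs = _category_probs(p.a, p.b, th)  # persons x K
            probs = probs / probs.sum(axis=1, keepdims=True)
            u = rng.random(design.n_persons)
            cum = np.cumsum(probs, axis=1)
            cols.append((u[:, None] < cum).argmax(axis=1) + 1.0)
            ids.append(f"{sub}_{i + 1:02d}")
    values = np.column_stack(cols)
    true_thetas = {sub: thetas[:, si] for si, sub in enumerate(subs)}
    return ResponseMatrix(values, tuple(ids)), true_thetas


def generate_clustered_embeddings(
    c: int,
    m: int,
    within: float,
    between: float,
    d: int = 64,
    seed: int = 0,
    n_unique: int = 0,
) -> tuple[EmbeddingMatrix, dict[str, int]]:
    """Embeddings with ``c`` redundancy clusters of ``m`` items each.

    Construction: with orthonormal directions g (shared), c_1..c_c (cluster
    centroids) and per-item isotropic noise, member vectors are

        v = sqrt(between) g + sqrt(within - between) c_j + sqrt(1 - within) eps,

    so expected cosine is ``within`` inside a cluster and ``between`` across
    clusters. Optional unique items omit the centroid term entirely. The
    realized mean similarities are self-checked to +-0.05 of the targets.

    Returns the matrix and a map item_id -> cluster index (-1 for unique).
    """
    if not (1.0 > within > between >= 0.0):
        raise ParameterError(
            f"need 1 > within ({within}) > between ({between}) >= 0"
        )
    if d < 2 * c:
        raise ParameterError(f"dimension d={d} too small for c={c} clusters")
    if d < c + n_unique + 2:
        raise ParameterError("dimension too small for the requested structure")
    rng = np.random.Generator(np.random.PCG64([seed, 2]))
    basis, _ = np.linalg.qr(rng.standard_normal((d, 1 + c + n_unique)))
    g = basis[:, 0]
    centroids = basis[:, 1 : 1 + c].T
    uniq_dirs = basis[:, 1 + c :].T

    def noise() -> np.ndarray:
        # isotropic noise restricted to the complement of the structural
        # subspace, so realized mean cosines stay on target at moderate d
        eps = rng.standard_normal(d)
        eps -= basis @ (basis.T @ eps)
        return eps / np.linalg.norm(eps)

    rows, ids, cluster_of = [], [], {}
    for j in range(c):
        for i in range(m):
            v = (
                np.sqrt(between) * g
                + np.sqrt(within - between) * centroids[j]
                + np.sqrt(1.0 - within) * noise()
            )
            iid = f"c{j + 1}_i{i + 1}"
            rows.append(v / np.linalg.norm(v))
            ids.append(iid)
            cluster_of[iid] = j
    for u in range(n_unique):
        v = np.sqrt(between) * g + np.sqrt(1.0 - between) * (
            0.9 * uniq_dirs[u] + 0.1 * noise()
        )
        iid = f"u{u + 1}"
        rows.append(v / np.linalg.norm(v))
        ids.append(iid)
        cluster_of[iid] = -1

    emb = EmbeddingMatrix(
        np.stack(rows), tuple(ids),
        f"synthetic-clustered(c={c}, m={m}, within={within}, between={between}, seed={seed})",
    )
    _self_check_clusters(emb, cluster_of, within, between)
    return emb, cluster_of


def _self_check_clusters(emb, cluster_of, within, between, tol=0.05):
    unit = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
    sim = unit @ unit.T
    labels = np.array([cluster_of[i] for i in emb.item_ids])
    win, btw = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if labels[i] == labels[j] and labels[i] >= 0:
                win.append(sim[i, j])
            elif labels[i] >= 0 and labels[j] >= 0:
                btw.append(sim[i, j])
    if win and abs(np.mean(win) - within) > tol:
        raise ValidationError(
            f"realized within-cluster cosine {np.mean(win):.3f} misses target {within}"
        )
    if btw and abs(np.mean(btw) - between) > tol:
        raise ValidationError(
            f"realized between-cluster cosine {np.mean(btw):.3f} misses target {between}"
        )


def _permutation_with_spearman(
    rng, base_ranks: np.ndarray, target: float, tol: float = 0.02,
    max_steps: int = 20_000,
) -> np.ndarray:
    """A permutation of 0..m-1 whose Spearman correlation with ``base_ranks``
    is within ``tol`` of ``target``; found by seeded random-swap hill climbing."""
    m = len(base_ranks)
    # achievable rank correlations form a grid of step 12/(m(m^2-1)); accept
    # the nearest half-step when that is coarser than the requested tol
    tol = max(tol, 7.0 / (m * (m * m - 1)))
    perm = np.argsort(base_ranks) if target >= 0 else np.argsort(-base_ranks)
    ranks = np.empty(m)
    ranks[perm] = np.arange(m)

    def rho(r):
        return float(np.corrcoef(base_ranks, r)[0, 1])

    cur = rho(ranks)
    best = ranks.copy()
    best_diff = abs(cur - target)
    stuck = 0
    for _ in range(max_steps):
        if best_diff <= tol:
            return best
        if stuck > 200:  # local optimum in single-swap space: restart
            rng.shuffle(ranks)
            cur = rho(ranks)
            stuck = 0
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        ranks[i], ranks[j] = ranks[j], ranks[i]
        new = rho(ranks)
        # sideways moves allowed: single swaps plateau easily at small m
        if abs(new - target) <= abs(cur - target):
            cur = new
            if abs(cur - target) < best_diff:
                best_diff = abs(cur - target)
                best = ranks.copy()
                stuck = 0
            else:
                stuck += 1
        else:
            ranks[i], ranks[j] = ranks[j], ranks[i]
            stuck += 1
    if best_diff <= tol:
        return best
    raise ParameterError(
        f"could not realize Spearman coupling {target} with {m} items"
    )


def generate_coupled_fixture(
    design: SimulationDesign, coupling: float, seed: int = 0
) -> tuple[ItemBank, ResponseMatrix, EmbeddingMatrix, dict]:
    """Joint fixture with a planted discrimination-vs-similarity correlation.

    Per subscale, item i's embedding is built as
    ``v_i = sqrt(s_i) g + sqrt(1 - s_i) u_i`` with orthonormal g, u_1..u_m,
    so pairwise cosines are exactly sqrt(s_i s_j) and the semantic similarity
    index is strictly increasing in the redundancy weight s_i. The design's
    discrimination values are then re-assigned across items so that the
    Spearman correlation between true a and the semantic index hits
    ``coupling`` (self-checked to +-0.1). Responses are simulated from the
    resulting model.

    Returns (bank, responses, embeddings, truth) where truth holds the true
    parameters, traits, redundancy weights and the realized coupling.
    """
    if abs(coupling) > 1:
        raise ParameterError("|coupling| must be <= 1")
    d = 64
    rng = np.random.Generator(np.random.PCG64([seed, 3]))

    new_items: dict[str, tuple[GRMItemParams, ...]] = {}
    rows, ids = [], []
    truth: dict = {"s": {}, "realized_coupling": {}, "a_true": {}, "coupling": coupling}
    for sub, params in design.items.items():
        m = len(params)
        if m < 4:
            raise ParameterError(
                f"subscale {sub!r} has {m} items; coupling needs >= 4"
            )
        if d < m + 2:
            raise ParameterError(f"too many items in {sub!r} for dimension {d}")
        s = np.linspace(0.15, 0.75, m)
        rng.shuffle(s)
        s_ranks = rankdata(s) - 1

        a_sorted = np.sort([p.a for p in params])
        a_ranks = _permutation_with_spearman(rng, s_ranks, coupling)
        a_assigned = a_sorted[a_ranks.astype(int)]

        basis, _ = np.linalg.qr(rng.standard_normal((d, m + 1)))
        g = basis[:, 0]
        u = basis[:, 1:].T
        sub_params = []
        for i, p in enumerate(params):
            v = np.sqrt(s[i]) * g + np.sqrt(1.0 - s[i]) * u[i]
            rows.append(v)
            ids.append(f"{sub}_{i + 1:02d}")
            sub_params.append(GRMItemParams(float(a_assigned[i]), p.b))
        new_items[sub] = tuple(sub_params)

        # exact population indices: index_i = sqrt(s_i) * mean_j sqrt(s_j)
        idx = np.array(
            [
                np.sqrt(s[i]) * np.mean(np.delete(np.sqrt(s), i))
                for i in range(m)
            ]
        )
        realized = float(
            np.corrcoef(rankdata(a_assigned), rankdata(idx))[0, 1]
        )
        if abs(realized - coupling) > 0.1:
            raise ValidationError(
                f"subscale {sub!r}: realized coupling {realized:.3f} misses "
                f"target {coupling}"
            )
        truth["s"][sub] = s
        truth["a_true"][sub] = a_assigned
        truth["realized_coupling"][sub] = realized

    coupled = SimulationDesign(
        design.n_persons, new_items, design.factor_corr, design.K,
        seed=design.seed,
    )
    responses, thetas = simulate_grm_responses(coupled)
    truth["thetas"] = thetas
    truth["params"] = new_items
    bank = coupled.bank()
    emb = EmbeddingMatrix(
        np.stack(rows), tuple(ids), f"synthetic-coupled(coupling={coupling}, seed={seed})"
    )
    return bank, responses, emb, truth
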