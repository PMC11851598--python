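"""Graded response model engine.

Samejima's graded response model (GRM) for ordered categories 1..K: item j
has a discrimination ``a_j > 0`` and ordered thresholds ``b_1 < ... <
b_{K-1}``; the probability of responding *above* category k is logistic,

    P*_k(theta) = 1 / (1 + exp(-a (theta - b_k))),

with P*_0 = 1 and P*_K = 0, so category k has probability
P*_{k-1} - P*_k. The logistic uses scaling constant D = 1 (the dominant
modern convention), so discriminations are on the same scale as the usual
"Baker band" interpretation thresholds.

Estimation is marginal maximum likelihood via EM: a standard-normal latent
trait is integrated over a fixed rectangle-rule quadrature grid; the E-step
computes posterior node weights per person, the M-step maximizes each item's
expected complete-data log-likelihood (quasi-Newton with an order-preserving
reparameterization). One latent dimension per call — fit each subscale
separately.

Also provided: EAP/MAP latent-trait scoring, item and test information, and
Baker's qualitative labels for discrimination magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .errors import (
    ConvergenceError,
    ParameterError,
    SchemaError,
    ValidationError,
)
from .item_bank import ResponseMatrix

__all__ = [
    "GRMItemParams",
    "GRMFitConfig",
    "GRMFitResult",
    "AbilityEstimates",
    "TIFCurve",
    "grm_category_probs",
    "fit_grm",
    "eap_theta",
    "item_information",
    "test_information",
    "classify_discrimination",
]

_A_LO, _A_HI = 0.05, 10.0  # discrimination bounds during optimization


@dataclass(frozen=True)
class GRMItemParams:
    """Discrimination ``a`` and strictly ordered thresholds ``b``."""

    a: float
    b: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValidationError(f"discrimination must be finite and positive, got {self.a}")
        if b.ndim != 1 or len(b) < 1:
            raise ValidationError("thresholds must be a 1-D array of length K-1 >= 1")
        if not np.all(np.diff(b) > 0):
            raise ValidationError(f"thresholds must be strictly increasing, got {b}")
        object.__setattr__(self, "a", float(self.a))
        object.__setattr__(self, "b", b)

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


@dataclass(frozen=True)
class GRMFitConfig:
    """Estimation settings. Defaults: 61 rectangle-rule nodes on [-5, 5]
    under a standard-normal prior (renormalized), tolerance 1e-4 on the
    maximum absolute parameter change, at most 500 EM iterations."""

    n_quad: int = 61
    quad_range: float = 5.0
    tol: float = 1e-4
    loglik_tol: float = 1e-7  # stall criterion for flat likelihood directions
    max_iter: int = 500
    compute_se: bool = True


@dataclass
class GRMFitResult:
    params: dict[str, GRMItemParams]
    se: dict[str, np.ndarray]  # per item: [se_a, se_b1, ..., se_b_{K-1}]
    loglik: float
    n_iter: int
    trace: list[float]  # marginal log-likelihood per EM iteration
    excluded: list[tuple[str, str]]  # (item_id, reason)
    converged: bool = True

    def param_table(self):
        import pandas as pd

        rows = {}
        for iid, p in self.params.items():
            rows[iid] = {"a": p.a, **{f"b{k + 1}": v for k, v in enumerate(p.b)}}
        return pd.DataFrame(rows).T


@dataclass(frozen=True)
class AbilityEstimates:
    """Per-person latent-trait point estimates and posterior SDs."""

    theta: np.ndarray
    se: np.ndarray
    all_missing: np.ndarray  # flag: person had no observed responses
    estimator: str = "eap"


@dataclass(frozen=True)
class TIFCurve:
    """Test information over a theta grid, with per-item curves."""

    grid: np.ndarray
    info: np.ndarray
    per_item: np.ndarray  # items x grid
    item_ids: tuple[str, ...]

    @property
    def argmax(self) -> float:
        return float(self.grid[int(np.argmax(self.info))])


def _boundary_probs(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """P*_k(theta) for k = 1..K-1, shaped (len(theta), K-1)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    return expit(a * (theta[:, None] - b[None, :]))


def _category_probs(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Category probabilities, shaped (len(theta), K)."""
    ps = _boundary_probs(a, b, theta)
    ones = np.ones((ps.shape[0], 1))
    zeros = np.zeros((ps.shape[0], 1))
    full = np.hstack([ones, ps, zeros])
    return np.maximum(full[:, :-1] - full[:, 1:], 0.0)


def grm_category_probs(p: GRMItemParams, theta: float, K: int) -> np.ndarray:
    """Probability of each response category 1..K at a single theta."""
    if K != p.n_categories:
        raise ValidationError(f"params imply K={p.n_categories}, got K={K}")
    probs = _category_probs(p.a, p.b, np.array([theta]))[0]
    return probs / probs.sum()


def _quad_grid(cfg: GRMFitConfig) -> tuple[np.ndarray, np.ndarray]:
    nodes = np.linspace(-cfg.quad_range, cfg.quad_range, cfg.n_quad)
    w = norm.pdf(nodes)
    return nodes, w / w.sum()


# --- M-step parameterization: psi = (log a, b1, log(b2-b1), ...) -------------

def _pack(a: float, b: np.ndarray) -> np.ndarray:
    d = np.diff(b)
    return np.concatenate([[np.log(a), b[0]], np.log(np.maximum(d, 1e-8))])


def _unpack(psi: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(psi[0]))
    b = np.concatenate([[psi[1]], psi[1] + np.cumsum(np.exp(psi[2:]))])
    return a, b


def _neg_q(psi: np.ndarray, r: np.ndarray, nodes: np.ndarray) -> float:
    a, b = _unpack(psi)
    probs = np.clip(_category_probs(a, b, nodes), 1e-10, 1.0)
    return -float(np.sum(r * np.log(probs)))


def _start_values(col: np.ndarray, K: int) -> tuple[float, np.ndarray]:
    """Threshold starts from marginal exceedance proportions at a = 1."""
    obs = col[~np.isnan(col)]
    b = []
    for k in range(1, K):
        p_above = np.clip(np.mean(obs > k), 1e-3, 1 - 1e-3)
        b.append(-np.log(p_above / (1 - p_above)))
    b = np.asarray(b, dtype=float)
    for i in range(1, len(b)):  # enforce strict ordering
        b[i] = max(b[i], b[i - 1] + 0.05)
    return 1.0, np.clip(b, -4.0, 4.0)


def _item_loglik_table(
    params: Sequence[tuple[float, np.ndarray]], nodes: np.ndarray, K: int
) -> np.ndarray:
    """log P(category | node) per item, shaped (items, Q, K)."""
    out = np.empty((len(params), len(nodes), K))
    for j, (a, b) in enumerate(params):
        out[j] = np.log(np.clip(_category_probs(a, b, nodes), 1e-10, 1.0))
    return out


def _person_logliks(
    logp: np.ndarray, x: np.ndarray
) -> np.ndarray:
    """Sum of item log-probabilities per (person, node); missing items skipped."""
    n, Q = x.shape[0], logp.shape[1]
    L = np.zeros((n, Q))
    for j in range(x.shape[1]):
        obs = ~np.isnan(x[:, j])
        cats = x[obs, j].astype(int) - 1
        L[obs] += logp[j][:, cats].T
    return L


def fit_grm(
    responses: ResponseMatrix,
    K: int,
    config: GRMFitConfig | None = None,
) -> GRMFitResult:
    """Marginal maximum likelihood EM estimation of GRM item parameters.

    Items with fewer than two observed categories are excluded (reported in
    ``result.excluded``). Missing responses contribute nothing to the
    likelihood for that item. Raises :class:`ConvergenceError` (carrying the
    last iterate and trace) if the EM loop hits ``max_iter``.
    """
    cfg = config or GRMFitConfig()
    x = responses.values
    ids = list(responses.item_ids)

    excluded: list[tuple[str, str]] = []
    keep: list[int] = []
    for j, iid in enumerate(ids):
        col = x[:, j]
        obs = col[~np.isnan(col)]
        n_cats = len(np.unique(obs))
        if n_cats < 2:
            reason = "all responses identical" if n_cats == 1 else "no observed responses"
            excluded.append((iid, reason))
        else:
            keep.append(j)
    if not keep:
        raise ValidationError("no estimable items (every item is degenerate)")
    x = x[:, keep]
    kept_ids = [ids[j] for j in keep]
    J = len(keep)

    nodes, w = _quad_grid(cfg)
    cur = [_start_values(x[:, j], K) for j in range(J)]
    psis = [_pack(a, b) for a, b in cur]
    trace: list[float] = []
    converged = False
    it = 0

    for it in range(1, cfg.max_iter + 1):
        # E-step
        logp = _item_loglik_table(cur, nodes, K)
        L = _person_logliks(logp, x)
        joint = L + np.log(w)[None, :]
        marg = logsumexp(joint, axis=1)
        trace.append(float(marg.sum()))
        post = np.exp(joint - marg[:, None])

        # M-step (per item, warm-started quasi-Newton)
        max_change = 0.0
        for j in range(J):
            r = np.zeros((len(nodes), K))
            col = x[:, j]
            for k in range(K):
                mask = col == k + 1
                if np.any(mask):
                    r[:, k] = post[mask].sum(axis=0)
            bounds = [(np.log(_A_LO), np.log(_A_HI)), (-8.0, 8.0)] + [
                (np.log(1e-4), np.log(16.0))
            ] * (K - 2)
            res = minimize(
                _neg_q,
                psis[j],
                args=(r, nodes),
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 50, "ftol": 1e-12, "gtol": 1e-8},
            )
            a_new, b_new = _unpack(res.x)
            a_old, b_old = cur[j]
            max_change = max(
                max_change,
                abs(a_new - a_old),
                float(np.max(np.abs(b_new - b_old))),
            )
            cur[j] = (a_new, b_new)
            psis[j] = res.x

        # converge on parameter stability, or on a stalled log-likelihood
        # (flat directions, e.g. thresholds of an a-at-bound item, can keep
        # drifting below any useful precision)
        stalled = len(trace) >= 2 and trace[-1] - trace[-2] < cfg.loglik_tol
        if max_change < cfg.tol or stalled:
            converged = True
            break

    params = {
        iid: GRMItemParams(a, _strictify(b)) for iid, (a, b) in zip(kept_ids, cur)
    }
    result = GRMFitResult(
        params=params,
        se={},
        loglik=trace[-1],
        n_iter=it,
        trace=trace,
        excluded=excluded,
        converged=converged,
    )
    if not converged:
        raise ConvergenceError(
            f"EM did not converge within {cfg.max_iter} iterations "
            f"(last max parameter change >= {cfg.tol})",
            last_iterate=result,
            trace=trace,
        )
    if cfg.compute_se:
        result.se = _empirical_se(x, kept_ids, cur, nodes, w, K)
    return result


def _strictify(b: np.ndarray) -> np.ndarray:
    """Nudge numerically tied thresholds apart so the ordering is strict."""
    b = b.copy()
    for i in range(1, len(b)):
        if b[i] <= b[i - 1]:
            b[i] = b[i - 1] + 1e-6
    return b


def _empirical_se(
    x: np.ndarray,
    ids: Sequence[str],
    params: Sequence[tuple[float, np.ndarray]],
    nodes: np.ndarray,
    w: np.ndarray,
    K: int,
) -> dict[str, np.ndarray]:
    """Outer-product-of-scores (BHHH) standard errors, per-item blocks.

    Per-person scores of the marginal likelihood are obtained from the
    Fisher identity (posterior-weighted complete-data scores), with the
    item-level derivatives taken by central differences.
    """
    logp = _item_loglik_table(params, nodes, K)
    L = _person_logliks(logp, x)
    joint = L + np.log(w)[None, :]
    post = np.exp(joint - logsumexp(joint, axis=1)[:, None])

    h = 1e-5
    out: dict[str, np.ndarray] = {}
    for j, iid in enumerate(ids):
        a, b = params[j]
        natural = np.concatenate([[a], b])
        scores = np.zeros((x.shape[0], len(natural)))
        col = x[:, j]
        obs = ~np.isnan(col)
        cats = col[obs].astype(int) - 1
        for p_idx in range(len(natural)):
            for sgn, store in ((1, "hi"), (-1, "lo")):
                pert = natural.copy()
                pert[p_idx] += sgn * h
                tbl = np.log(
                    np.clip(_category_probs(pert[0], np.sort(pert[1:]), nodes), 1e-10, 1)
                )
                vals = tbl[:, cats].T  # (n_obs, Q)
                if store == "hi":
                    hi = vals
                else:
                    lo = vals
            dlogp = (hi - lo) / (2 * h)
            scores[obs, p_idx] = np.sum(post[obs] * dlogp, axis=1)
        info = scores.T @ scores
        try:
            cov = np.linalg.inv(info)
            out[iid] = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:  # pragma: no cover
            out[iid] = np.full(len(natural), np.nan)
    return out


def eap_theta(
    params: Mapping[str, GRMItemParams],
    responses: ResponseMatrix,
    n_quad: int = 61,
    quad_range: float = 5.0,
    method: str = "eap",
) -> AbilityEstimates:
    """Posterior mean (EAP) or mode (MAP) of theta under an N(0, 1) prior.

    Persons with all responses missing get theta = 0, se = 1 and a flag.
    """
    missing_params = [i for i in responses.item_ids if i not in params]
    if missing_params:
        raise SchemaError(f"no GRM parameters for item(s): {missing_params}")
    if method not in ("eap", "map"):
        raise ParameterError(f"unknown ability estimator {method!r}")

    K = next(iter(params.values())).n_categories
    plist = [(params[i].a, params[i].b) for i in responses.item_ids]
    nodes = np.linspace(-quad_range, quad_range, n_quad)
    w = norm.pdf(nodes)
    w = w / w.sum()

    logp = _item_loglik_table(plist, nodes, K)
    L = _person_logliks(logp, responses.values)
    joint = L + np.log(w)[None, :]
    post = np.exp(joint - logsumexp(joint, axis=1)[:, None])

    if method == "eap":
        theta = post @ nodes
        var = np.maximum(post @ nodes**2 - theta**2, 1e-12)
        se = np.sqrt(var)
    else:
        idx = np.argmax(joint, axis=1)
        theta = nodes[idx]
        var = np.maximum(post @ nodes**2 - (post @ nodes) ** 2, 1e-12)
        se = np.sqrt(var)

    all_missing = np.all(np.isnan(responses.values), axis=1)
    theta = np.where(all_missing, 0.0, theta)
    se = np.where(all_missing, 1.0, se)
    return AbilityEstimates(theta, se, all_missing, estimator=method)


def item_information(p: GRMItemParams, theta) -> np.ndarray | float:
    """Fisher information of one item at theta.

    I(theta) = a^2 * sum_k (Q_{k-1} - Q_k)^2 / P_k with Q_k = P*_k (1 - P*_k)
    and P_k the category probability, summed over categories with positive
    probability.
    """
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    ps = _boundary_probs(p.a, p.b, theta_arr)
    full = np.hstack(
        [np.ones((len(theta_arr), 1)), ps, np.zeros((len(theta_arr), 1))]
    )
    q = full * (1.0 - full)  # P*(1-P*) per boundary
    pk = full[:, :-1] - full[:, 1:]
    num = (q[:, :-1] - q[:, 1:]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pk > 1e-12, num / np.maximum(pk, 1e-12), 0.0)
    info = p.a**2 * terms.sum(axis=1)
    return info if np.ndim(theta) else float(info[0])


def test_information(
    params: Mapping[str, GRMItemParams], grid: Sequence[float]
) -> TIFCurve:
    """Sum of item information curves over an ascending theta grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("theta grid must be non-empty")
    if not np.all(np.diff(grid) > 0):
        raise ParameterError("theta grid must be strictly ascending")
    ids = tuple(params)
    per_item = np.stack([item_information(params[i], grid) for i in ids])
    return TIFCurve(grid, per_item.sum(axis=0), per_item, ids)


_BAKER_BANDS = [
    (0.25, "very low"),
    (0.65, "low"),
    (1.35, "moderate"),
    (1.70, "high"),
    (np.inf, "very high"),
]


def classify_discrimination(a: float) -> str:
    """Baker's qualitative label for a discrimination value.

    Bands: very low [0, 0.25), low [0.25, 0.65), moderate [0.65, 1.35),
    high [1.35, 1.70), very high [1.70, inf).
    """
    if a < 0:
        raise ValidationError(f"discrimination must be >= 0, got {a}")
    for upper, label in _BAKER_BANDS:
        if a < upper:
            return label
    raise AssertionError("unreachable")  # pragma: no cover
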