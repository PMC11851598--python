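"""Polychoric correlations and DWLS confirmatory factor analysis.

Likert responses are treated as discretizations of latent bivariate-normal
variables. Polychoric correlations are estimated in two stages (Olsson):
stage 1 fixes each item's thresholds from its inverse-normal cumulative
margins; stage 2 maximizes the bivariate-normal contingency-table likelihood
over the correlation. The confirmatory factor model (congeneric: each item
loads on exactly one factor, factor variances fixed to 1) is then fit by
diagonally weighted least squares: squared correlation residuals weighted by
the inverse asymptotic variance of each polychoric estimate.

The chi-square reported is the unscaled (n-1) * F_min; mean/variance
adjusted (WLSMV-style) statistics are not implemented. Fit indices follow
the standard definitions of CFI, TLI, RMSEA and SRMR against an
independence baseline with identical thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import owens_t
from scipy.stats import norm

from .errors import (
    ConfigError,
    ConvergenceError,
    EstimationError,
    ValidationError,
)
from .item_bank import ResponseMatrix

__all__ = [
    "PolychoricMatrix",
    "CFAModel",
    "FitIndices",
    "FitRule",
    "ACO_STOP_RULE",
    "HU_BENTLER_RULE",
    "bvn_cdf",
    "polychoric_pair",
    "polychoric_matrix",
    "fit_cfa_dwls",
    "baseline_model",
    "fit_indices",
    "meets_fit_thresholds",
]

_RHO_BOUND = 0.999


def bvn_cdf(h, k, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF P(X <= h, Y <= k), vectorized in h, k.

    Uses Owen's T-function identity, exact up to the accuracy of
    ``scipy.special.owens_t``. Infinite limits reduce to the univariate CDF.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(np.clip(rho, -0.999999, 0.999999))

    out = np.empty(h.shape)
    neg_inf_h = np.isneginf(h)
    neg_inf_k = np.isneginf(k)
    pos_inf_h = np.isposinf(h)
    pos_inf_k = np.isposinf(k)
    edge = neg_inf_h | neg_inf_k | pos_inf_h | pos_inf_k

    out[neg_inf_h | neg_inf_k] = 0.0
    both_pos = pos_inf_h & pos_inf_k
    out[both_pos] = 1.0
    only_h = pos_inf_h & ~pos_inf_k & ~neg_inf_k
    out[only_h] = norm.cdf(k[only_h])
    only_k = pos_inf_k & ~pos_inf_h & ~neg_inf_h
    out[only_k] = norm.cdf(h[only_k])

    fin = ~edge
    hf = h[fin]
    kf = k[fin]
    # nudge exact zeros so the Owen decomposition is well defined
    hf = np.where(hf == 0.0, 1e-13, hf)
    kf = np.where(kf == 0.0, 1e-13, kf)
    s = np.sqrt(1.0 - rho * rho)
    ah = (kf - rho * hf) / (hf * s)
    ak = (hf - rho * kf) / (kf * s)
    beta = np.where(hf * kf < 0.0, 0.5, 0.0)
    val = (
        0.5 * (norm.cdf(hf) + norm.cdf(kf))
        - owens_t(hf, ah)
        - owens_t(kf, ak)
        - beta
    )
    out[fin] = val
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class PolychoricPair:
    rho: float
    thresholds_x: np.ndarray
    thresholds_y: np.ndarray
    asy_var: float
    n: int
    boundary: bool = False


def _thresholds(codes: np.ndarray, n_levels: int) -> np.ndarray:
    counts = np.bincount(codes, minlength=n_levels).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return norm.ppf(cum)


def _cell_probs(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    gx = np.concatenate([[-np.inf], tx, [np.inf]])
    gy = np.concatenate([[-np.inf], ty, [np.inf]])
    grid = bvn_cdf(gx[:, None], gy[None, :], rho)
    return grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]


def polychoric_pair(
    x: Sequence[float], y: Sequence[float], K: int
) -> PolychoricPair:
    """Two-stage ML polychoric correlation for one ordinal pair.

    Categories with zero marginal frequency are collapsed out before
    thresholding. The correlation is searched on [-0.999, 0.999]; a solution
    at the boundary (e.g. perfect concordance) is clamped and flagged, with
    its asymptotic variance marked unreliable (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    xs, ys = x[ok], y[ok]
    n = len(xs)
    if n < 2:
        raise EstimationError("fewer than 2 complete observations for the pair")

    # reindex to observed levels so thresholds stay strictly increasing
    lev_x = np.unique(xs)
    lev_y = np.unique(ys)
    if len(lev_x) < 2 or len(lev_y) < 2:
        raise EstimationError(
            "polychoric correlation undefined: a variable shows a single category"
        )
    cx = np.searchsorted(lev_x, xs)
    cy = np.searchsorted(lev_y, ys)
    table = np.zeros((len(lev_x), len(lev_y)))
    np.add.at(table, (cx, cy), 1.0)

    tx = _thresholds(cx, len(lev_x))
    ty = _thresholds(cy, len(lev_y))

    def nll(rho: float) -> float:
        probs = np.clip(_cell_probs(tx, ty, rho), 1e-12, 1.0)
        return -float(np.sum(table * np.log(probs)))

    res = minimize_scalar(
        nll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    boundary = abs(rho) >= _RHO_BOUND - 1e-4
    if boundary:
        rho = float(np.sign(rho) * _RHO_BOUND)
        asy_var = float("nan")
    else:
        h = 5e-4
        d2 = (nll(rho + h) - 2.0 * nll(rho) + nll(rho - h)) / h**2
        asy_var = 1.0 / d2 if d2 > 0 else float("nan")
    return PolychoricPair(rho, tx, ty, asy_var, n, boundary)


@dataclass(frozen=True)
class PolychoricMatrix:
    """Pairwise-complete polychoric correlation matrix with DWLS weights."""

    rho: np.ndarray
    asy_var: np.ndarray  # per-pair asymptotic variance (NaN on diagonal)
    thresholds: tuple[np.ndarray, ...]  # per item, from its full margin
    item_ids: tuple[str, ...]
    n_pairs: np.ndarray
    boundary: np.ndarray  # per-pair boundary flags

    def __post_init__(self) -> None:
        r = np.asarray(self.rho, dtype=float)
        if not np.allclose(r, r.T, atol=1e-10):
            raise ValidationError("polychoric matrix not symmetric within 1e-10")
        if np.nanmax(np.abs(r)) > 1.0 + 1e-12:
            raise ValidationError("polychoric correlations must lie in [-1, 1]")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def subset(self, item_ids: Sequence[str]) -> "PolychoricMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        ix = np.ix_(idx, idx)
        return PolychoricMatrix(
            self.rho[ix],
            self.asy_var[ix],
            tuple(self.thresholds[i] for i in idx),
            tuple(item_ids),
            self.n_pairs[ix],
            self.boundary[ix],
        )


def polychoric_matrix(
    responses: ResponseMatrix, K: int, min_pairs: int = 50
) -> PolychoricMatrix:
    """Assemble the full item x item polychoric matrix pairwise-complete."""
    p = responses.n_items
    vals = responses.values
    rho = np.eye(p)
    avar = np.full((p, p), np.nan)
    npairs = np.zeros((p, p), dtype=int)
    bnd = np.zeros((p, p), dtype=bool)
    for i, j in combinations(range(p), 2):
        n_ok = int(np.sum(~np.isnan(vals[:, i]) & ~np.isnan(vals[:, j])))
        if n_ok < min_pairs:
            raise EstimationError(
                f"pair ({responses.item_ids[i]}, {responses.item_ids[j]}) has only "
                f"{n_ok} complete observations (< {min_pairs})"
            )
        pr = polychoric_pair(vals[:, i], vals[:, j], K)
        rho[i, j] = rho[j, i] = pr.rho
        avar[i, j] = avar[j, i] = pr.asy_var
        npairs[i, j] = npairs[j, i] = pr.n
        bnd[i, j] = bnd[j, i] = pr.boundary
    thresholds = []
    for j in range(p):
        col = vals[:, j]
        obs = col[~np.isnan(col)]
        lev = np.unique(obs)
        codes = np.searchsorted(lev, obs)
        thresholds.append(_thresholds(codes, len(lev)))
    return PolychoricMatrix(
        rho, avar, tuple(thresholds), responses.item_ids, npairs, bnd
    )


@dataclass
class CFAModel:
    """A fitted congeneric ordinal CFA."""

    structure: Mapping[str, str]
    loadings: Mapping[str, float]
    factor_names: tuple[str, ...]
    factor_corr: np.ndarray
    chi2: float
    df: int
    fit_min: float
    n: int
    implied: np.ndarray
    residuals: np.ndarray
    item_ids: tuple[str, ...]
    heywood: bool = False
    converged: bool = True


@dataclass(frozen=True)
class FitIndices:
    cfi: float
    tli: float | None
    rmsea: float | None
    srmr: float
    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    n: int

    def as_dict(self) -> dict:
        return {
            "cfi": self.cfi,
            "tli": self.tli,
            "rmsea": self.rmsea,
            "srmr": self.srmr,
            "chi2": self.chi2,
            "df": self.df,
            "chi2_baseline": self.chi2_baseline,
            "df_baseline": self.df_baseline,
            "n": self.n,
        }


def _weights(poly: PolychoricMatrix) -> np.ndarray:
    """Per-pair DWLS weights: asymptotic variance of the sqrt(n)-scaled
    polychoric estimate (n_pair * var(rho_hat)), so that (n-1) * F_min is on
    the chi-square scale. Unreliable entries (boundary pairs, non-positive
    curvature) fall back to 1."""
    w = poly.asy_var * np.maximum(poly.n_pairs, 1)
    bad = ~np.isfinite(w) | (w <= 0)
    w[bad] = 1.0
    return w


def fit_cfa_dwls(
    poly: PolychoricMatrix, structure: Mapping[str, str], n: int
) -> CFAModel:
    """Fit a congeneric factor model to a polychoric matrix by DWLS.

    Minimizes sum over unique pairs of (r - sigma)^2 / asy_var, where sigma
    is the model-implied correlation lambda_i lambda_j phi_{f(i) f(j)}.
    Factor variances are fixed to 1. chi2 = (n - 1) * F_min.
    """
    ids = poly.item_ids
    missing = [i for i in ids if i not in structure]
    if missing:
        raise ValidationError(f"structure lacks factor assignment for: {missing}")
    factors: list[str] = []
    for i in ids:
        if structure[i] not in factors:
            factors.append(structure[i])
    f_idx = np.array([factors.index(structure[i]) for i in ids])
    p = len(ids)
    nf = len(factors)

    counts = np.bincount(f_idx, minlength=nf)
    if np.any(counts < 2) or (nf == 1 and p < 3):
        raise ValidationError(
            "model under-identified: need >= 3 items per factor, or >= 2 with "
            "correlated factors"
        )

    iu = np.triu_indices(p, 1)
    r_obs = poly.rho[iu]
    w = _weights(poly)[iu]
    n_phi = nf * (nf - 1) // 2
    phi_iu = np.triu_indices(nf, 1)

    def unpack(x):
        lam = x[:p]
        phi = np.eye(nf)
        if n_phi:
            phi[phi_iu] = x[p:]
            phi = phi + phi.T - np.eye(nf)
        return lam, phi

    def implied(lam, phi):
        return (lam[:, None] * lam[None, :]) * phi[np.ix_(f_idx, f_idx)]

    def objective(x):
        lam, phi = unpack(x)
        e = r_obs - implied(lam, phi)[iu]
        return float(np.sum(e * e / w))

    bounds = [(-1.5, 1.5)] * p + [(-0.999, 0.999)] * n_phi
    best = None
    for lam0, phi0 in ((0.7, 0.3), (0.4, 0.0), (0.9, 0.6)):
        x0 = np.concatenate([np.full(p, lam0), np.full(n_phi, phi0)])
        res = minimize(
            objective, x0, jac=None, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and res.fun < 1e8:
            break
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("DWLS optimization failed", trace=None)

    lam, phi = unpack(best.x)
    sig = implied(lam, phi)
    free = p + n_phi
    df = p * (p - 1) // 2 - free
    if df < 0:
        raise ValidationError(f"negative degrees of freedom ({df}); model not identified")
    fmin = float(best.fun)
    resid = poly.rho - sig
    np.fill_diagonal(resid, 0.0)
    return CFAModel(
        structure=dict(structure),
        loadings={iid: float(l) for iid, l in zip(ids, lam)},
        factor_names=tuple(factors),
        factor_corr=phi,
        chi2=float((n - 1) * fmin),
        df=df,
        fit_min=fmin,
        n=n,
        implied=sig,
        residuals=resid,
        item_ids=ids,
        heywood=bool(np.any(np.abs(lam) > 1.0)),
        converged=bool(best.success),
    )


def baseline_model(poly: PolychoricMatrix, n: int) -> CFAModel:
    """Independence baseline: all correlations zero, identical thresholds."""
    p = poly.n_items
    iu = np.triu_indices(p, 1)
    w = _weights(poly)[iu]
    fmin = float(np.sum(poly.rho[iu] ** 2 / w))
    resid = poly.rho.copy()
    np.fill_diagonal(resid, 0.0)
    return CFAModel(
        structure={i: "none" for i in poly.item_ids},
        loadings={i: 0.0 for i in poly.item_ids},
        factor_names=(),
        factor_corr=np.zeros((0, 0)),
        chi2=float((n - 1) * fmin),
        df=p * (p - 1) // 2,
        fit_min=fmin,
        n=n,
        implied=np.eye(p),
        residuals=resid,
        item_ids=poly.item_ids,
    )


def fit_indices(model: CFAModel, baseline: CFAModel) -> FitIndices:
    """CFI, TLI, RMSEA and SRMR for a fitted model vs its independence baseline.

    With df = 0 (saturated model) TLI and RMSEA are undefined and reported
    as None, never NaN.
    """
    chi2, df = model.chi2, model.df
    chi2_b, df_b = baseline.chi2, baseline.df

    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den

    if df == 0 or df_b == 0:
        tli = None
        rmsea = None if df == 0 else _rmsea(chi2, df, model.n)
    else:
        ratio_b = chi2_b / df_b
        tli = (ratio_b - chi2 / df) / (ratio_b - 1.0) if ratio_b != 1.0 else None
        rmsea = _rmsea(chi2, df, model.n)

    p = len(model.item_ids)
    iu = np.triu_indices(p, 1)
    srmr = float(np.sqrt(np.mean(model.residuals[iu] ** 2)))
    return FitIndices(
        cfi=float(np.clip(cfi, 0.0, 1.0)),
        tli=None if tli is None else float(tli),
        rmsea=rmsea,
        srmr=srmr,
        chi2=chi2,
        df=df,
        chi2_baseline=chi2_b,
        df_baseline=df_b,
        n=model.n,
    )


def _rmsea(chi2: float, df: int, n: int) -> float:
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))


_OPS = {
    ">": lambda v, t: v > t,
    ">=": lambda v, t: v >= t,
    "<": lambda v, t: v < t,
    "<=": lambda v, t: v <= t,
}

FitRule = tuple[tuple[str, str, float], ...]

#: Stopping rule used by the ant-colony search: strict CFI/TLI/RMSEA cutoffs.
ACO_STOP_RULE: FitRule = (("cfi", ">", 0.95), ("tli", ">", 0.95), ("rmsea", "<", 0.05))

#: Hu-Bentler adequacy rule: CFI, TLI >= .95 and SRMR <= .08.
HU_BENTLER_RULE: FitRule = (("cfi", ">=", 0.95), ("tli", ">=", 0.95), ("srmr", "<=", 0.08))


def meets_fit_thresholds(
    fit: FitIndices, rule: FitRule = ACO_STOP_RULE
) -> tuple[bool, dict[str, bool]]:
    """Evaluate a conjunction of index comparisons against the fit.

    An index that is not applicable (None, e.g. RMSEA of a saturated model)
    counts as satisfied: a saturated model fits perfectly.
    """
    verdicts: dict[str, bool] = {}
    d = fit.as_dict()
    for name, op, threshold in rule:
        if name not in d:
            raise ConfigError(f"unknown fit index {name!r} in threshold rule")
        if op not in _OPS:
            raise ConfigError(f"unknown comparison operator {op!r}")
        value = d[name]
        verdicts[name] = True if value is None else bool(_OPS[op](value, threshold))
    return all(verdicts.values()), verdicts
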