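"""Cross-method evaluation of short forms.

Runs the whole comparison pipeline: abbreviate a scale by each requested
method (semantic, ant colony, genetic), fit the graded response model to the
original and each short form per subscale, score persons, overlay test
information, correlate ability estimates across forms (Pearson), relate
item parameters to semantic similarity indices (Spearman), and fit the
ordinal CFA for each form.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cfa import (
    HU_BENTLER_RULE,
    baseline_model,
    fit_cfa_dwls,
    fit_indices,
    meets_fit_thresholds,
    polychoric_matrix,
)
from .embedding import EmbeddingMatrix
from .errors import ParameterError, SchemaError, UndefinedStatisticError
from .grm import AbilityEstimates, GRMFitConfig, eap_theta, fit_grm, test_information
from .item_bank import ItemBank, ResponseMatrix, reverse_score
from .search import ACOConfig, GAConfig, aco_abbreviate, ga_abbreviate
from .semantic import (
    SelectionResult,
    select_semantic,
    semantic_similarity_indices,
    similarity_matrix,
)

__all__ = [
    "pearson",
    "spearman",
    "compare_thetas",
    "param_similarity_table",
    "ComparisonReport",
    "run_comparison",
]

log = logging.getLogger(__name__)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; undefined for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ParameterError("pearson needs two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    if np.array_equal(x, y):  # identical score vectors correlate exactly 1
        return 1.0
    return float(stats.pearsonr(x, y).statistic)


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks for ties) with two-sided p.

    For n <= 9 the p-value is exact, from the full permutation distribution
    of one rank vector; for larger n the usual t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("spearman needs two equal-length vectors")
    n = len(x)
    if n < 4:
        raise ParameterError("spearman needs length >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("spearman undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_rho(rx, ry)
    if n <= 9:
        perms = np.array(list(permutations(range(n))))
        permed = rx[perms]  # (n!, n)
        ryc = ry - ry.mean()
        rxc = permed - permed.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc**2).sum(axis=1) * (ryc**2).sum())
        rhos = (rxc @ ryc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def compare_thetas(
    forms: Mapping[str, AbilityEstimates],
) -> pd.DataFrame:
    """Pearson correlation matrix of ability estimates across forms.

    All forms must score the same persons (same vector length).
    """
    names = list(forms)
    lengths = {len(forms[n].theta) for n in names}
    if len(lengths) != 1:
        raise SchemaError(f"person counts differ across forms: {lengths}")
    mat = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = pearson(forms[names[i]].theta, forms[names[j]].theta)
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)


def param_similarity_table(
    params: Mapping[str, "GRMItemParams"],
    indices: pd.Series,
    bank: ItemBank,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman rho (and two-sided p) of a and each b_k vs the semantic index.

    One row per parameter (a, b1, ..., b_{K-1}) per subscale; rows with
    p < alpha are flagged significant.
    """
    rows = []
    for sub in bank.subscales:
        ids = [it.item_id for it in bank.items_in(sub) if it.item_id in params]
        missing = [i for i in ids if i not in indices]
        if missing:
            raise SchemaError(f"no semantic index for item(s): {missing}")
        idx = np.array([indices[i] for i in ids])
        K = params[ids[0]].n_categories
        specs = [("a", np.array([params[i].a for i in ids]))] + [
            (f"b{k + 1}", np.array([params[i].b[k] for i in ids]))
            for k in range(K - 1)
        ]
        for label, vals in specs:
            try:
                rho, p = spearman(vals, idx)
            except UndefinedStatisticError as exc:
                raise UndefinedStatisticError(
                    f"subscale {sub!r} row {label!r}: {exc}"
                ) from exc
            rows.append(
                {
                    "subscale": sub,
                    "parameter": label,
                    "rho": rho,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Everything the cross-method comparison produces."""

    selections: dict[str, SelectionResult]
    grm_params: dict[str, dict[str, pd.DataFrame]]  # form -> subscale -> table
    tif: dict[str, dict[str, pd.DataFrame]]  # form -> subscale -> grid/info
    theta_correlations: dict[str, pd.DataFrame]  # subscale -> form x form
    param_similarity: pd.DataFrame
    fit: dict[str, dict]  # form -> fit indices + verdicts
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "selections": {
                m: {
                    "method": s.method,
                    "selected": {k: list(v) for k, v in s.selected.items()},
                    "seed": s.seed,
                }
                for m, s in self.selections.items()
            },
            "grm_params": {
                f: {s: t.to_dict("index") for s, t in per.items()}
                for f, per in self.grm_params.items()
            },
            "theta_correlations": {
                s: df.to_dict("index") for s, df in self.theta_correlations.items()
            },
            "param_similarity": self.param_similarity.to_dict("records"),
            "fit": self.fit,
            "provenance": self.provenance,
        }

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=2, default=_jsonable) + "\n",
            encoding="utf-8",
        )
        self.param_similarity.to_csv(out / "param_similarity.csv", index=False)
        for sub, df in self.theta_correlations.items():
            df.to_csv(out / f"theta_correlations_{sub}.csv")
        for form, per in self.tif.items():
            for sub, df in per.items():
                df.to_csv(out / f"tif_{form}_{sub}.csv", index=False)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_comparison(
    bank: ItemBank,
    responses: ResponseMatrix,
    embeddings: EmbeddingMatrix,
    k: int,
    seed: int = 0,
    methods: Sequence[str] = ("semantic", "aco", "ga"),
    grm_config: GRMFitConfig | None = None,
    aco_config: ACOConfig | None = None,
    ga_config: GAConfig | None = None,
    tif_grid: np.ndarray | None = None,
    min_pairs: int = 50,
) -> ComparisonReport:
    """Run the full cross-method comparison on one dataset.

    Stages: reverse-score, select items per method, fit the GRM per form and
    subscale, score persons (EAP), compute test information, correlate
    ability estimates across forms, relate original-form item parameters to
    semantic similarity indices, and fit the two-factor ordinal CFA per form.
    """
    for sub in bank.subscales:
        size = len(bank.items_in(sub))
        if k > size:
            raise ParameterError(f"k={k} exceeds subscale {sub!r} size {size}")
    unknown = set(methods) - {"semantic", "aco", "ga"}
    if unknown:
        raise ParameterError(f"unknown method(s): {sorted(unknown)}")

    grm_cfg = grm_config or GRMFitConfig(compute_se=False)
    t0 = time.time()
    scored = responses if responses.scored else reverse_score(responses, bank)

    sim = similarity_matrix(embeddings)
    indices = semantic_similarity_indices(sim, bank)

    selections: dict[str, SelectionResult] = {}
    if "semantic" in methods:
        log.info("selecting by semantic uniqueness")
        selections["semantic"] = select_semantic(indices, bank, k)
    if "aco" in methods:
        log.info("selecting by ant colony optimization")
        cfg = aco_config or ACOConfig(seed=seed)
        selections["aco"] = aco_abbreviate(scored, bank, k, cfg)
    if "ga" in methods:
        log.info("selecting by genetic algorithm")
        cfg = ga_config or GAConfig(seed=seed)
        selections["ga"] = ga_abbreviate(scored, bank, k, cfg)

    forms: dict[str, dict[str, list[str]]] = {
        "original": {s: [it.item_id for it in bank.items_in(s)] for s in bank.subscales}
    }
    for m, sel in selections.items():
        forms[m] = {s: list(ids) for s, ids in sel.selected.items()}

    grid = tif_grid if tif_grid is not None else np.arange(-4.0, 4.0001, 0.1)
    grm_tables: dict[str, dict[str, pd.DataFrame]] = {}
    tif_tables: dict[str, dict[str, pd.DataFrame]] = {}
    thetas: dict[str, dict[str, AbilityEstimates]] = {}
    original_params: dict[str, object] = {}

    for form, per_sub in forms.items():
        grm_tables[form] = {}
        tif_tables[form] = {}
        thetas[form] = {}
        for sub, ids in per_sub.items():
            log.info("fitting GRM: form=%s subscale=%s (%d items)", form, sub, len(ids))
            sub_resp = scored.subset(ids)
            fit = fit_grm(sub_resp, bank.n_categories, grm_cfg)
            grm_tables[form][sub] = fit.param_table()
            ability = eap_theta(fit.params, sub_resp)
            thetas[form][sub] = ability
            tifc = test_information(fit.params, grid)
            tif_tables[form][sub] = pd.DataFrame(
                {"theta": tifc.grid, "information": tifc.info}
            )
            if form == "original":
                original_params.update(fit.params)

    theta_corrs = {
        sub: compare_thetas({f: thetas[f][sub] for f in forms})
        for sub in bank.subscales
    }
    par_sim = param_similarity_table(original_params, indices, bank)

    fits: dict[str, dict] = {}
    for form, per_sub in forms.items():
        all_ids = [i for s in per_sub.values() for i in s]
        structure = {i: bank.subscale_of()[i] for i in all_ids}
        poly = polychoric_matrix(
            scored.subset(all_ids), bank.n_categories, min_pairs=min_pairs
        )
        model = fit_cfa_dwls(poly, structure, scored.n_persons)
        fi = fit_indices(model, baseline_model(poly, scored.n_persons))
        ok, verdicts = meets_fit_thresholds(fi, HU_BENTLER_RULE)
        fits[form] = {
            "indices": fi.as_dict(),
            "meets_hu_bentler": ok,
            "verdicts": verdicts,
            "heywood": model.heywood,
        }

    report = ComparisonReport(
        selections=selections,
        grm_params=grm_tables,
        tif=tif_tables,
        theta_correlations=theta_corrs,
        param_similarity=par_sim,
        fit=fits,
        provenance={
            "k": k,
            "seed": seed,
            "methods": list(methods),
            "n_persons": scored.n_persons,
            "n_items": len(bank.items),
            "embedding_backend": embeddings.backend_tag,
            "theta_estimator": "eap",
            "wall_time_s": round(time.time() - t0, 2),
        },
    )
    return report
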