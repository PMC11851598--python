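"""Polychoric correlations, DWLS factor analysis, and fit indices."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from scaletrim import (
    ConfigError,
    EstimationError,
    ResponseMatrix,
    baseline_model,
    fit_cfa_dwls,
    fit_indices,
    meets_fit_thresholds,
    polychoric_matrix,
    polychoric_pair,
)
from scaletrim.cfa import (
    ACO_STOP_RULE,
    CFAModel,
    FitIndices,
    HU_BENTLER_RULE,
    PolychoricMatrix,
    bvn_cdf,
)


def _ordinal_pair(rho, n, seed, cuts_x=(-1.2, -0.4, 0.4, 1.2), cuts_y=None):
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    x = np.digitize(z[:, 0], list(cuts_x)) + 1.0
    y = np.digitize(z[:, 1], list(cuts_y or cuts_x)) + 1.0
    return x, y


class TestBvnCdf:
    def test_matches_scipy_bivariate_normal(self):
        """Owen's-T evaluation agrees with scipy's bivariate normal CDF."""
        pts = [(0.5, -0.3), (1.2, 1.1), (0.0, 0.7), (-2.0, 0.1), (0.0, 0.0)]
        for rho in (-0.95, -0.5, 0.0, 0.3, 0.8, 0.99):
            ref = multivariate_normal(cov=[[1, rho], [rho, 1]])
            for h, k in pts:
                assert bvn_cdf(h, k, rho) == pytest.approx(
                    ref.cdf([h, k]), abs=5e-7
                )

    def test_infinite_limits_reduce_to_univariate(self):
        from scipy.stats import norm

        assert bvn_cdf(np.inf, 0.3, 0.5) == pytest.approx(norm.cdf(0.3), abs=1e-12)
        assert bvn_cdf(-np.inf, 0.3, 0.5) == 0.0
        assert bvn_cdf(np.inf, np.inf, 0.5) == 1.0


class TestPolychoricPair:
    def test_independent_variables_near_zero(self):
        x, y = _ordinal_pair(0.0, 5000, 0)
        assert abs(polychoric_pair(x, y, 5).rho) < 0.05

    def test_median_split_recovers_rho(self):
        """Dichotomized bivariate normal with rho=0.6 recovers 0.6 +- 0.05."""
        x, y = _ordinal_pair(0.6, 5000, 1, cuts_x=(0.0,))
        assert polychoric_pair(x, y, 2).rho == pytest.approx(0.6, abs=0.05)

    @pytest.mark.parametrize("rho", [-0.6, 0.3, 0.8])
    def test_five_category_recovery(self, rho):
        x, y = _ordinal_pair(rho, 5000, 2)
        assert polychoric_pair(x, y, 5).rho == pytest.approx(rho, abs=0.05)

    def test_perfect_concordance_clamps_with_flag(self):
        x, _ = _ordinal_pair(0.3, 500, 3)
        pr = polychoric_pair(x, x, 5)
        assert pr.rho == pytest.approx(0.999)
        assert pr.boundary
        assert np.isnan(pr.asy_var)

    def test_single_category_variable_rejected(self):
        x = np.full(100, 3.0)
        y = np.tile([1.0, 2.0], 50)
        with pytest.raises(EstimationError, match="single category"):
            polychoric_pair(x, y, 5)

    def test_error_shrinks_with_sample_size(self):
        """Estimation error roughly halves per 4x n (consistency)."""
        errs = []
        for n in (1250, 5000, 20000):
            reps = [
                abs(polychoric_pair(*_ordinal_pair(0.5, n, seed), 5).rho - 0.5)
                for seed in range(4)
            ]
            errs.append(np.mean(reps))
        assert errs[2] < errs[0]


class TestPolychoricMatrix:
    def test_independent_items_small_offdiagonals(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(1, 6, size=(5000, 3)).astype(float)
        pm = polychoric_matrix(ResponseMatrix(vals, ("a", "b", "c"), True), 5)
        off = pm.rho[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 0.06)

    def test_row_permutation_invariance_and_symmetry(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(1, 6, size=(400, 3)).astype(float)
        rm = ResponseMatrix(vals, ("a", "b", "c"), True)
        pm1 = polychoric_matrix(rm, 5)
        perm = rng.permutation(400)
        pm2 = polychoric_matrix(ResponseMatrix(vals[perm], ("a", "b", "c"), True), 5)
        np.testing.assert_array_equal(pm1.rho, pm2.rho)
        np.testing.assert_array_equal(pm1.rho, pm1.rho.T)

    def test_pair_floor_names_the_pair(self):
        rng = np.random.default_rng(6)
        vals = rng.integers(1, 6, size=(30, 2)).astype(float)
        with pytest.raises(EstimationError, match=r"\(a, b\)"):
            polychoric_matrix(ResponseMatrix(vals, ("a", "b"), True), 5)


def _toy_poly(rho_matrix, n=1000):
    p = rho_matrix.shape[0]
    return PolychoricMatrix(
        rho_matrix,
        np.full((p, p), 0.5 / n),
        tuple(np.array([-1.0, 0.0, 1.0]) for _ in range(p)),
        tuple(f"i{j}" for j in range(p)),
        np.full((p, p), n),
        np.zeros((p, p), dtype=bool),
    )


class TestDWLS:
    def test_zero_residual_fixed_point(self):
        """Model-implied polychorics return chi2 = 0 and the generating values."""
        lam = np.array([0.8, 0.7, 0.6, 0.5])
        sigma = np.outer(lam, lam)
        np.fill_diagonal(sigma, 1.0)
        model = fit_cfa_dwls(_toy_poly(sigma), {f"i{j}": "g" for j in range(4)}, 1000)
        assert model.chi2 == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(
            sorted(model.loadings.values()), sorted(lam), atol=1e-4
        )

    def test_two_factor_recovery(self):
        """Loadings 0.7 and factor correlation 0.5 recovered within 0.05."""
        rng = np.random.default_rng(7)
        n = 5000
        F = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
        cols, ids = [], []
        for f in range(2):
            for j in range(4):
                y = 0.7 * F[:, f] + np.sqrt(1 - 0.49) * rng.standard_normal(n)
                cols.append(np.digitize(y, [-1.0, -0.3, 0.5, 1.1]) + 1.0)
                ids.append(f"f{f}_{j}")
        rm = ResponseMatrix(np.column_stack(cols), tuple(ids), True)
        pm = polychoric_matrix(rm, 5)
        model = fit_cfa_dwls(pm, {i: i.split("_")[0] for i in ids}, n)
        for lam in model.loadings.values():
            assert lam == pytest.approx(0.7, abs=0.05)
        assert model.factor_corr[0, 1] == pytest.approx(0.5, abs=0.05)
        assert not model.heywood

    def test_just_identified_three_items(self):
        """3-item single factor is saturated: df=0, chi2 ~ 0, RMSEA/TLI n/a."""
        rng = np.random.default_rng(8)
        n = 1000
        F = rng.standard_normal(n)
        cols = [
            np.digitize(0.7 * F + 0.7 * rng.standard_normal(n), [-0.8, 0.3, 1.0]) + 1.0
            for _ in range(3)
        ]
        rm = ResponseMatrix(np.column_stack(cols), ("a", "b", "c"), True)
        pm = polychoric_matrix(rm, 4)
        model = fit_cfa_dwls(pm, {"a": "g", "b": "g", "c": "g"}, n)
        assert model.df == 0
        assert model.chi2 < 1e-6
        fi = fit_indices(model, baseline_model(pm, n))
        assert fi.rmsea is None and fi.tli is None
        assert fi.cfi == 1.0
        ok, verdicts = meets_fit_thresholds(fi, ACO_STOP_RULE)
        assert ok  # not-applicable indices count as satisfied

    def test_under_identified_rejected(self):
        sigma = np.eye(2)
        with pytest.raises(Exception, match="identified"):
            fit_cfa_dwls(_toy_poly(sigma), {"i0": "g", "i1": "g"}, 500)


class TestFitIndices:
    def test_worked_formula_example(self):
        """chi2=100, df=50, chi2_b=1000, df_b=60, n=1001 -> CFI=.94681, RMSEA=.03162."""
        mk = lambda chi2, df: CFAModel(
            {}, {}, (), np.eye(0), chi2, df, 0.0, 1001,
            np.eye(2), np.zeros((2, 2)), ("x", "y"),
        )
        fi = fit_indices(mk(100.0, 50), mk(1000.0, 60))
        assert fi.cfi == pytest.approx(0.94681, abs=1e-5)
        assert fi.rmsea == pytest.approx(0.03162, abs=1e-5)

    def test_perfect_fit_limits(self):
        mk = lambda chi2, df, resid: CFAModel(
            {}, {}, (), np.eye(0), chi2, df, 0.0, 500, np.eye(3), resid,
            ("x", "y", "z"),
        )
        fi = fit_indices(mk(0.0, 10, np.zeros((3, 3))), mk(900.0, 15, np.zeros((3, 3))))
        assert fi.cfi == 1.0
        assert fi.tli >= 1.0
        assert fi.srmr == 0.0
        assert fi.rmsea == 0.0

    def test_srmr_invariant_to_item_order(self):
        rng = np.random.default_rng(9)
        resid = rng.normal(0, 0.05, size=(4, 4))
        resid = (resid + resid.T) / 2
        np.fill_diagonal(resid, 0.0)
        mk = lambda r, ids: CFAModel(
            {}, {}, (), np.eye(0), 50.0, 10, 0.0, 500, np.eye(4), r, ids
        )
        base = fit_indices(mk(resid, ("a", "b", "c", "d")), mk(resid, ("a", "b", "c", "d")))
        perm = [2, 0, 3, 1]
        r2 = resid[np.ix_(perm, perm)]
        permuted = fit_indices(mk(r2, ("c", "a", "d", "b")), mk(r2, ("c", "a", "d", "b")))
        assert base.srmr == pytest.approx(permuted.srmr, abs=1e-15)


class TestThresholdRules:
    def _fi(self, cfi, tli, rmsea, srmr=0.05):
        return FitIndices(cfi, tli, rmsea, srmr, 10.0, 5, 100.0, 10, 500)

    def test_paper_style_pass(self):
        ok, _ = meets_fit_thresholds(self._fi(0.986, 0.984, 0.04), ACO_STOP_RULE)
        assert ok

    def test_tli_below_cutoff_fails(self):
        ok, verdicts = meets_fit_thresholds(self._fi(0.951, 0.944, 0.04), ACO_STOP_RULE)
        assert not ok and not verdicts["tli"]

    def test_strict_boundaries_fail_at_threshold(self):
        ok, verdicts = meets_fit_thresholds(self._fi(0.95, 0.95, 0.05), ACO_STOP_RULE)
        assert not ok
        assert not any(verdicts.values())

    def test_hu_bentler_boundaries_inclusive(self):
        ok, _ = meets_fit_thresholds(self._fi(0.95, 0.95, 0.2, srmr=0.08), HU_BENTLER_RULE)
        assert ok

    def test_unknown_index_is_config_error(self):
        with pytest.raises(ConfigError, match="gfi"):
            meets_fit_thresholds(self._fi(0.9, 0.9, 0.1), (("gfi", ">", 0.9),))


def test_submodel_srmr_on_well_fitting_fixture():
    """Dropping an item from a well-fitting congeneric model leaves the
    refit SRMR no worse (checked empirically on a simulated fixture)."""
    rng = np.random.default_rng(10)
    n = 3000
    F = rng.standard_normal(n)
    lams = [0.8, 0.75, 0.7, 0.65, 0.6]
    cols = [
        np.digitize(l * F + np.sqrt(1 - l * l) * rng.standard_normal(n),
                    [-1.0, -0.3, 0.5, 1.1]) + 1.0
        for l in lams
    ]
    ids = tuple(f"i{j}" for j in range(5))
    rm = ResponseMatrix(np.column_stack(cols), ids, True)
    pm = polychoric_matrix(rm, 5)
    full = fit_cfa_dwls(pm, {i: "g" for i in ids}, n)
    full_srmr = fit_indices(full, baseline_model(pm, n)).srmr
    for drop in ids:
        keep = [i for i in ids if i != drop]
        sub_pm = pm.subset(keep)
        sub = fit_cfa_dwls(sub_pm, {i: "g" for i in keep}, n)
        sub_srmr = fit_indices(sub, baseline_model(sub_pm, n)).srmr
        assert sub_srmr <= full_srmr + 2e-3
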