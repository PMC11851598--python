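"""Graded response model: probabilities, estimation, scoring, information."""

import numpy as np
import pytest
from scipy.stats import norm

from scaletrim import (
    GRMFitConfig,
    GRMItemParams,
    ResponseMatrix,
    ValidationError,
    classify_discrimination,
    eap_theta,
    fit_grm,
    grm_category_probs,
    item_information,
)
from scaletrim import test_information as total_information
from scaletrim.grm import _category_probs


class TestCategoryProbs:
    def test_dichotomous_at_threshold(self):
        p = GRMItemParams(1.0, np.array([0.0]))
        np.testing.assert_allclose(grm_category_probs(p, 0.0, 2), [0.5, 0.5])

    def test_three_category_worked_example(self):
        """a=2, b=(-1,1), theta=0: boundary logistics give (.11920,.76159,.11920)."""
        p = GRMItemParams(2.0, np.array([-1.0, 1.0]))
        np.testing.assert_allclose(
            grm_category_probs(p, 0.0, 3), [0.11920, 0.76159, 0.11920], atol=5e-6
        )

    def test_simplex_over_random_draws(self):
        """Probabilities are nonnegative and sum to 1 within 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            K = rng.integers(2, 7)
            a = rng.uniform(0.1, 4.0)
            b = np.sort(rng.uniform(-3, 3, size=K - 1))
            b += np.arange(K - 1) * 1e-3  # guarantee strict ordering
            theta = rng.uniform(-5, 5, size=50)
            probs = _category_probs(a, np.asarray(b), theta)
            assert np.all(probs >= 0)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            GRMItemParams(1.0, np.array([1.0, -1.0]))

    def test_nonpositive_discrimination_rejected(self):
        with pytest.raises(ValidationError):
            GRMItemParams(0.0, np.array([0.0]))


class TestInformation:
    def test_vanishing_discrimination(self):
        p = GRMItemParams(0.01, np.array([-1.0, 0.0, 1.0]))
        assert item_information(p, 0.0) <= 1e-3

    def test_dichotomous_peak_value(self):
        """K=2: information at theta=b is a^2 * P(1-P) = 0.25 for a=1."""
        p = GRMItemParams(1.0, np.array([0.7]))
        assert item_information(p, 0.7) == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("theta", [-2.0, -0.5, 0.0, 1.3])
    def test_matches_score_function_derivative(self, theta):
        """I(theta) = sum_k P_k'(theta)^2 / P_k(theta), P' by central differences."""
        p = GRMItemParams(1.7, np.array([-1.2, 0.1, 0.8, 2.0]))
        h = 1e-6
        hi = _category_probs(p.a, p.b, np.array([theta + h]))[0]
        lo = _category_probs(p.a, p.b, np.array([theta - h]))[0]
        mid = _category_probs(p.a, p.b, np.array([theta]))[0]
        deriv = (hi - lo) / (2 * h)
        expected = np.sum(deriv**2 / mid)
        assert item_information(p, theta) == pytest.approx(expected, abs=1e-5)

    def test_tif_additivity_and_monotonicity(self):
        p = GRMItemParams(1.5, np.array([-0.5, 0.5]))
        q = GRMItemParams(0.8, np.array([-1.5, 1.5]))
        grid = np.linspace(-3, 3, 61)
        single = total_information({"i1": p}, grid)
        double = total_information({"i1": p, "i2": p}, grid)
        np.testing.assert_allclose(double.info, 2 * single.info, atol=1e-12)
        full = total_information({"i1": p, "i2": q}, grid)
        assert np.all(single.info <= full.info + 1e-15)
        assert np.all(full.per_item.sum(axis=0) == full.info)

    def test_peak_location_follows_thresholds(self):
        """High-discrimination items centered near theta=-1 peak in (-2, 0)."""
        params = {
            f"i{j}": GRMItemParams(2.2, np.array([-1.0]) + 0.1 * j - 0.2)
            for j in range(5)
        }
        curve = total_information(params, np.linspace(-4, 4, 161))
        assert -2.0 < curve.argmax < 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(Exception):
            total_information({"i": GRMItemParams(1.0, np.array([0.0]))}, [])


class TestClassifyDiscrimination:
    @pytest.mark.parametrize(
        "a,label",
        [
            (0.1, "very low"),
            (0.25, "low"),
            (0.65, "moderate"),
            (1.34, "moderate"),
            (1.35, "high"),
            (1.55, "high"),
            (1.69, "high"),
            (1.70, "very high"),
            (2.58, "very high"),
        ],
    )
    def test_band_boundaries(self, a, label):
        assert classify_discrimination(a) == label

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            classify_discrimination(-0.1)


def _simulate(params, thetas, K, rng):
    cols = []
    for p in params:
        probs = _category_probs(p.a, p.b, thetas)
        u = rng.random(len(thetas))
        cols.append((u[:, None] < np.cumsum(probs, axis=1)).argmax(axis=1) + 1.0)
    return np.column_stack(cols)


class TestFitGRM:
    def test_em_ascends_and_duplication_invariance(self):
        rng = np.random.default_rng(5)
        params = [
            GRMItemParams(1.5, np.array([-1.0, 0.0, 1.0, 2.0])),
            GRMItemParams(2.0, np.array([-1.5, -0.5, 0.5, 1.5])),
            GRMItemParams(1.0, np.array([-2.0, -1.0, 0.5, 1.8])),
            GRMItemParams(1.8, np.array([-0.8, 0.2, 1.0, 2.2])),
        ]
        theta = rng.standard_normal(400)
        vals = _simulate(params, theta, 5, rng)
        ids = tuple(f"q{j}" for j in range(4))
        rm = ResponseMatrix(vals, ids, scored=True)
        cfg = GRMFitConfig(compute_se=False)
        fit = fit_grm(rm, 5, cfg)
        assert np.all(np.diff(fit.trace) >= -1e-8), "EM log-likelihood must ascend"

        doubled = ResponseMatrix(np.vstack([vals, vals]), ids, scored=True)
        fit2 = fit_grm(doubled, 5, cfg)
        for iid in ids:
            assert fit2.params[iid].a == pytest.approx(fit.params[iid].a, abs=2e-3)
            np.testing.assert_allclose(
                fit2.params[iid].b, fit.params[iid].b, atol=2e-3
            )

    def test_noise_item_pinned_near_lower_bound(self):
        rng = np.random.default_rng(6)
        params = [
            GRMItemParams(0.01, np.array([-1.0, 0.0, 1.0, 2.0])),
            GRMItemParams(1.8, np.array([-1.0, 0.0, 1.0, 2.0])),
            GRMItemParams(1.5, np.array([-1.5, -0.5, 0.5, 1.5])),
            GRMItemParams(1.2, np.array([-2.0, -0.8, 0.8, 1.8])),
            GRMItemParams(2.1, np.array([-0.6, 0.2, 1.1, 2.0])),
        ]
        theta = rng.standard_normal(800)
        rm = ResponseMatrix(
            _simulate(params, theta, 5, rng),
            ("noise", "s1", "s2", "s3", "s4"),
            scored=True,
        )
        fit = fit_grm(rm, 5, GRMFitConfig(compute_se=False))
        assert fit.params["noise"].a < 0.3

    def test_degenerate_item_excluded_with_notice(self):
        rng = np.random.default_rng(7)
        good = [
            GRMItemParams(1.5, np.array([-1.0, 0.0, 1.0, 2.0])),
            GRMItemParams(1.8, np.array([-1.5, -0.5, 0.5, 1.5])),
            GRMItemParams(1.2, np.array([-2.0, -0.8, 0.8, 1.8])),
        ]
        theta = rng.standard_normal(300)
        vals = _simulate(good, theta, 5, rng)
        vals = np.column_stack([vals, np.full(300, 3.0)])
        rm = ResponseMatrix(vals, ("a", "b", "c", "const"), scored=True)
        fit = fit_grm(rm, 5, GRMFitConfig(compute_se=False))
        assert ("const", "all responses identical") in fit.excluded
        assert "const" not in fit.params

    def test_quadrature_refinement_stable(self):
        rng = np.random.default_rng(8)
        params = [
            GRMItemParams(1.6, np.array([-1.0, 0.0, 1.0])),
            GRMItemParams(1.2, np.array([-1.5, 0.2, 1.4])),
            GRMItemParams(2.0, np.array([-0.5, 0.5, 1.5])),
        ]
        theta = rng.standard_normal(500)
        rm = ResponseMatrix(
            _simulate(params, theta, 4, rng), ("a", "b", "c"), scored=True
        )
        fit61 = fit_grm(rm, 4, GRMFitConfig(n_quad=61, compute_se=False))
        fit121 = fit_grm(rm, 4, GRMFitConfig(n_quad=121, compute_se=False))
        for iid in ("a", "b", "c"):
            assert abs(fit61.params[iid].a - fit121.params[iid].a) < 1e-3
            assert np.max(np.abs(fit61.params[iid].b - fit121.params[iid].b)) < 1e-3

    def test_standard_errors_shrink_with_n(self):
        rng = np.random.default_rng(9)
        params = [
            GRMItemParams(1.6, np.array([-1.0, 0.0, 1.0])),
            GRMItemParams(1.2, np.array([-1.5, 0.2, 1.4])),
            GRMItemParams(2.0, np.array([-0.5, 0.5, 1.5])),
        ]
        ids = ("a", "b", "c")
        ses = []
        for n in (300, 1200):
            theta = rng.standard_normal(n)
            rm = ResponseMatrix(_simulate(params, theta, 4, rng), ids, scored=True)
            fit = fit_grm(rm, 4, GRMFitConfig(compute_se=True))
            ses.append(np.mean([fit.se[i][0] for i in ids]))
        assert ses[1] < ses[0]


class TestEAP:
    def test_flat_likelihood_returns_prior_mean(self):
        params = {"q1": GRMItemParams(0.051, np.array([-1.0, 1.0]))}
        rm = ResponseMatrix(np.array([[1.0], [3.0]]), ("q1",), scored=True)
        est = eap_theta(params, rm)
        np.testing.assert_allclose(est.theta, 0.0, atol=0.05)

    def test_symmetric_pattern_scores_zero(self):
        params = {
            "q1": GRMItemParams(1.5, np.array([-1.0, 1.0])),
            "q2": GRMItemParams(1.5, np.array([-1.0, 1.0])),
        }
        rm = ResponseMatrix(np.array([[2.0, 2.0]]), ("q1", "q2"), scored=True)
        est = eap_theta(params, rm)
        assert est.theta[0] == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_integration(self):
        """EAP on the quadrature grid agrees with a 10,001-point trapezoid
        integration of the exact posterior within 1e-4."""
        params = {
            "q1": GRMItemParams(1.8, np.array([-1.2, -0.2, 0.8, 1.6])),
            "q2": GRMItemParams(1.1, np.array([-2.0, -0.8, 0.3, 1.2])),
            "q3": GRMItemParams(2.4, np.array([-0.9, 0.0, 1.1, 2.1])),
        }
        patterns = [[1.0, 2.0, 3.0], [5.0, 5.0, 4.0], [3.0, np.nan, 2.0]]
        rm = ResponseMatrix(np.array(patterns), ("q1", "q2", "q3"), scored=True)
        est = eap_theta(params, rm, n_quad=961, quad_range=6.0)

        grid = np.linspace(-6, 6, 10_001)
        for i, pattern in enumerate(patterns):
            logpost = norm.logpdf(grid)
            for iid, x in zip(("q1", "q2", "q3"), pattern):
                if np.isnan(x):
                    continue
                p = params[iid]
                probs = _category_probs(p.a, p.b, grid)[:, int(x) - 1]
                logpost += np.log(np.clip(probs, 1e-300, 1))
            w = np.exp(logpost - logpost.max())
            w /= np.trapezoid(w, grid)
            expected = np.trapezoid(grid * w, grid)
            assert est.theta[i] == pytest.approx(expected, abs=1e-4)

    def test_all_missing_person_flagged(self):
        params = {"q1": GRMItemParams(1.5, np.array([0.0]))}
        rm = ResponseMatrix(np.array([[np.nan], [1.0]]), ("q1",), scored=True)
        est = eap_theta(params, rm)
        assert est.all_missing[0] and not est.all_missing[1]
        assert est.theta[0] == 0.0 and est.se[0] == 1.0

    def test_map_estimator_available(self):
        params = {"q1": GRMItemParams(1.5, np.array([-1.0, 1.0]))}
        rm = ResponseMatrix(np.array([[3.0]]), ("q1",), scored=True)
        est = eap_theta(params, rm, method="map")
        assert est.estimator == "map"
        assert est.theta[0] > 0
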