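"""Conditional logistic likelihood, Newton fit, OR reporting, curve mode."""

import numpy as np
import pandas as pd
import pytest

from ccburden.basis import CrossBasisSpec, SplineSpec
from ccburden.clogit import (
    DesignMatrix,
    build_design,
    conditional_loglik,
    exposure_response_curve,
    fit,
    or_per_increment,
)
from ccburden.design import build_matched_sets


def dm_from_blocks(X, is_case, set_sizes, term_map=None):
    """Assemble a DesignMatrix directly from per-set blocks."""
    X = np.asarray(X, dtype=float)
    starts = np.cumsum([0, *set_sizes[:-1]])
    return DesignMatrix(
        X=X if X.ndim == 2 else X[:, None],
        is_case=np.asarray(is_case, dtype=bool),
        set_start=np.asarray(starts),
        set_id=np.arange(len(set_sizes)),
        colnames=[f"x{i}" for i in range((X.ndim == 2 and X.shape[1]) or 1)],
        term_map=term_map or {"pm": [0]},
    )


def paired_dm(diffs):
    """One covariate, pairs where the case-control difference is given."""
    rows, is_case = [], []
    for d in diffs:
        rows += [d, 0.0]
        is_case += [True, False]
    return dm_from_blocks(np.array(rows), is_case, [2] * len(diffs))


class TestConditionalLoglik:
    def test_uniform_at_beta_zero(self):
        """With beta=0 each of the 5 member days is equally likely."""
        rng = np.random.default_rng(0)
        n_sets = 7
        X = rng.normal(size=(5 * n_sets, 3))
        is_case = np.tile([True, False, False, False, False], n_sets)
        dm = dm_from_blocks(X, is_case, [5] * n_sets, term_map={"pm": [0]})
        ll = conditional_loglik(np.zeros(3), dm)
        assert ll == pytest.approx(-n_sets * np.log(5), abs=1e-12)

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4))
        is_case = np.tile([True, False, False, False], 5)
        dm = dm_from_blocks(X, is_case, [4] * 5, term_map={"pm": [0]})
        beta = rng.normal(scale=0.5, size=4)
        _, grad = conditional_loglik(beta, dm, order=1)
        eps = 1e-6
        for j in range(4):
            e = np.zeros(4)
            e[j] = eps
            num = (conditional_loglik(beta + e, dm)
                   - conditional_loglik(beta - e, dm)) / (2 * eps)
            assert grad[j] == pytest.approx(num, abs=1e-6)

    def test_information_matches_finite_difference_of_gradient(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 2))
        is_case = np.tile([True, False, False], 5)
        dm = dm_from_blocks(X, is_case, [3] * 5, term_map={"pm": [0]})
        beta = np.array([0.3, -0.2])
        _, _, info = conditional_loglik(beta, dm, order=2)
        eps = 1e-6
        for j in range(2):
            e = np.zeros(2)
            e[j] = eps
            _, gp = conditional_loglik(beta + e, dm, order=1)
            _, gm = conditional_loglik(beta - e, dm, order=1)
            np.testing.assert_allclose(-(gp - gm) / (2 * eps), info[:, j], atol=1e-5)


class TestFit:
    def test_three_pair_toy_has_closed_form_mle(self):
        """Case-control differences (+1, +1, -1): the score equation gives
        beta_hat = log 2 exactly."""
        res = fit(paired_dm([1.0, 1.0, -1.0]))
        assert res.converged and not res.separation
        assert res.beta[0] == pytest.approx(np.log(2.0), abs=1e-8)

    def test_three_pair_toy_matches_grid_search(self):
        """MLE within 1e-4 of a brute-force grid maximum over [-5, 5]."""
        dm = paired_dm([1.0, 1.0, -1.0])
        res = fit(dm)
        grid = np.arange(-5.0, 5.0 + 1e-9, 1e-4)
        lls = [conditional_loglik(np.array([b]), dm) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert abs(res.beta[0] - best) <= 1e-4
        assert res.loglik >= max(lls) - 1e-10

    def test_symmetric_pairs_give_zero(self):
        res = fit(paired_dm([1.0, -1.0]))
        assert res.beta[0] == pytest.approx(0.0, abs=1e-10)

    def test_estimates_invariant_to_within_set_constant_shifts(self):
        """Adding a per-set constant to any covariate cannot change the
        conditional-likelihood estimates (the shift cancels in the ratio)."""
        rng = np.random.default_rng(3)
        n_sets, size = 40, 4
        X = rng.normal(size=(n_sets * size, 2))
        is_case = np.zeros(n_sets * size, dtype=bool)
        is_case[::size] = True
        dm = dm_from_blocks(X, is_case, [size] * n_sets, term_map={"pm": [0]})
        res1 = fit(dm)

        shifts = np.repeat(rng.normal(scale=5.0, size=n_sets), size)
        X2 = X.copy()
        X2[:, 0] += shifts
        dm2 = dm_from_blocks(X2, is_case, [size] * n_sets, term_map={"pm": [0]})
        res2 = fit(dm2)
        np.testing.assert_allclose(res1.beta, res2.beta, atol=1e-8)
        np.testing.assert_allclose(res1.loglik, res2.loglik, atol=1e-8)

    def test_observed_information_positive_definite_at_mle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(120, 3))
        is_case = np.zeros(120, dtype=bool)
        is_case[::4] = True
        dm = dm_from_blocks(X, is_case, [4] * 30, term_map={"pm": [0]})
        res = fit(dm)
        assert not res.separation
        _, _, info = conditional_loglik(res.beta, dm, order=2)
        assert np.all(np.linalg.eigvalsh(info) > 0)
        assert np.all(np.linalg.eigvalsh(res.vcov) > 0)

    def test_separation_is_flagged_not_divergent(self):
        """Case exposure strictly above every referent's: monotone
        likelihood, no finite MLE."""
        res = fit(paired_dm([1.0, 2.0, 0.5, 1.5]))
        assert res.separation and not res.converged
        assert np.all(np.isnan(res.beta))

    def test_matches_statsmodels_conditional_logit(self, medium_data):
        """Cross-implementation oracle: coefficients agree to 1e-6 with
        statsmodels' ConditionalLogit on a ~1,000-set fixture."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        _, panel, cases = medium_data
        cases = cases.iloc[:1000]
        sets, _ = build_matched_sets(cases, panel)
        dm = build_design(sets, temp=CrossBasisSpec(), holiday=True)
        res = fit(dm)
        assert res.converged

        groups = np.repeat(np.arange(dm.n_sets), dm.set_sizes())
        sm_fit = ConditionalLogit(
            dm.is_case.astype(int), dm.X, groups=groups
        ).fit(method="newton", maxiter=500, tol=1e-12, disp=0)
        np.testing.assert_allclose(res.beta, sm_fit.params, atol=1e-6)


class TestOrReporting:
    def test_null_coefficient_gives_symmetric_unit_or(self, ):
        dm = paired_dm([1.0, -1.0])
        res = fit(dm)
        out = or_per_increment(res, "pm", increment=10.0)
        assert out["or"] == pytest.approx(1.0, abs=1e-9)
        # CI symmetric about 1 on the log scale
        assert np.log(out["ci_low"]) == pytest.approx(-np.log(out["ci_high"]), abs=1e-9)

    def test_ci_endpoints_reproduce_by_hand(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(90, 1))
        is_case = np.zeros(90, dtype=bool)
        is_case[::3] = True
        dm = dm_from_blocks(X, is_case, [3] * 30, term_map={"pm": [0]})
        res = fit(dm)
        out = or_per_increment(res, "pm", increment=10.0)
        b, se = res.beta[0], np.sqrt(res.vcov[0, 0])
        z = 1.959963984540054  # Phi^-1(0.975)
        assert out["ci_low"] == pytest.approx(np.exp(10 * (b - z * se)), rel=1e-12)
        assert out["ci_high"] == pytest.approx(np.exp(10 * (b + z * se)), rel=1e-12)

    def test_headline_or_round_trip(self):
        """beta = log(1.07)/10 per unit reports OR 1.07 per 10 units."""
        res_beta = np.array([np.log(1.07) / 10.0])
        dm = paired_dm([1.0])
        res = fit(dm)
        res.beta = res_beta
        res.vcov = np.array([[0.0]])
        out = or_per_increment(res, "pm")
        assert out["or"] == pytest.approx(1.07, rel=1e-12)

    def test_spline_term_refused(self, small_data):
        _, panel, cases = small_data
        sets, _ = build_matched_sets(cases.iloc[:200], panel)
        dm = build_design(sets, pm=SplineSpec(df=4), temp=None, holiday=False)
        res = fit(dm)
        with pytest.raises(ValueError, match="spline"):
            or_per_increment(res, "pm")


@pytest.fixture(scope="module")
def spline_fit(small_data):
    _, panel, cases = small_data
    sets, _ = build_matched_sets(cases, panel)
    dm = build_design(sets, pm=SplineSpec(df=4), temp=CrossBasisSpec())
    return dm, fit(dm)


class TestExposureResponseCurve:
    def test_unit_or_with_zero_width_ci_at_reference(self, spline_fit):
        dm, res = spline_fit
        ref = float(np.median(dm.pm_values))
        curve = exposure_response_curve(res, dm, reference=ref,
                                        grid=np.array([ref, ref + 5]))
        assert curve["or"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert curve["se_log_or"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_linear_truth_recovered_within_uncertainty(self, spline_fit, small_data):
        """Data generated with an exactly log-linear effect: the flexible
        curve stays within simulation error of the fitted line on the
        interior of the exposure range."""
        cfg, panel, cases = small_data
        dm, res = spline_fit
        sets, _ = build_matched_sets(cases, panel)
        linear_fit = fit(build_design(sets, pm="linear", temp=CrossBasisSpec()))
        slope = linear_fit.beta[linear_fit.term_map["pm"][0]]

        lo, hi = np.quantile(dm.pm_values, [0.1, 0.9])
        ref = float(np.quantile(dm.pm_values, 0.5))
        grid = np.linspace(lo, hi, 25)
        curve = exposure_response_curve(res, dm, reference=ref, grid=grid)
        line = slope * (grid - ref)
        # pointwise: curve within its own 95% band of the linear fit
        z = 1.96
        assert np.all(np.abs(curve["log_or"] - line) <= z * curve["se_log_or"] + 1e-9)

    def test_guideline_levels_reportable(self, spline_fit):
        """The curve evaluates at the WHO (15) and NAAQS/KAS (35) guideline
        levels used as reference lines in the flexible-association figure."""
        dm, res = spline_fit
        ref = float(np.min(dm.pm_values))
        curve = exposure_response_curve(res, dm, reference=ref,
                                        grid=np.array([15.0, 35.0]))
        assert np.all(np.isfinite(curve[["or", "ci_low", "ci_high"]]))

    def test_linear_fit_has_no_curve(self, small_data):
        _, panel, cases = small_data
        sets, _ = build_matched_sets(cases.iloc[:200], panel)
        dm = build_design(sets, pm="linear", temp=None)
        res = fit(dm)
        with pytest.raises(ValueError, match="linear"):
            exposure_response_curve(res, dm, reference=20.0)


class TestBuildDesign:
    def test_flags_degenerate_columns(self, small_data):
        _, panel, cases = small_data
        sets, _ = build_matched_sets(cases.iloc[:300], panel)
        sets = sets.copy()
        sets["holiday"] = False  # constant inside every set
        dm = build_design(sets, temp=None, holiday=True)
        assert "holiday" in dm.degenerate_cols
        assert "pm" not in dm.degenerate_cols

    def test_rejects_sets_without_unique_case(self, small_data):
        _, panel, cases = small_data
        sets, _ = build_matched_sets(cases.iloc[:50], panel)
        broken = sets.copy()
        broken["is_case"] = False
        with pytest.raises(ValueError, match="exactly one case"):
            build_design(broken, temp=None)
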