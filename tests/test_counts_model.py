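"""Poisson fitting, model enumeration, cross-validation and pseudo-R².

The IRLS fitter is checked against two independent oracles: the
closed-form MLE of the saturated two-group Poisson model (group means)
and statsmodels' GLM implementation.
"""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ctc_emt.counts_model import (
    CvMetrics,
    DesignSpec,
    build_design,
    crossval_model,
    enumerate_models,
    fit_multiresponse,
    fit_poisson,
    irr_table,
    nagelkerke_r2,
    partial_r2,
    poisson_loglik,
    round_counts,
    select_best,
)
from ctc_emt.phenotyping import PHENOTYPES

TOY_Y = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
TOY_X = np.column_stack([np.ones(5), np.array([0.0, 0.0, 0.0, 1.0, 1.0])])


def toy_loglik(y, mu):
    return float(np.sum(y * np.log(mu) - mu - np.log([math.factorial(int(v)) for v in y])))


class TestFitPoisson:
    def test_two_group_closed_form(self):
        """Single binary predictor: the MLE is the pair of group means, so
        the IRR is their ratio (5/2 = 2.5) and the intercept rate is 2."""
        fit = fit_poisson(TOY_Y, TOY_X)
        assert fit.converged
        assert math.exp(fit.beta[0]) == pytest.approx(2.0, abs=1e-8)
        assert math.exp(fit.beta[1]) == pytest.approx(2.5, abs=1e-8)

    def test_intercept_only_rate_is_sample_mean(self):
        y = np.array([0, 1, 3, 2, 5, 1], dtype=float)
        fit = fit_poisson(y, np.ones((6, 1)))
        assert math.exp(fit.beta[0]) == pytest.approx(y.mean(), abs=1e-10)

    def test_matches_statsmodels(self):
        """Coefficients, standard errors and log-likelihood agree with the
        independent GLM implementation on random data."""
        rng = np.random.default_rng(0)
        n = 200
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.normal(0, 0.5, n)])
        y = rng.poisson(np.exp(0.3 + 0.5 * X[:, 1] - 0.4 * X[:, 2]))
        fit = fit_poisson(y, X)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_ratio_of_group_means_property(self):
        """On any single-binary-predictor dataset with both group means
        positive, the fitted IRR equals the ratio of group means (1e−8)."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n0, n1 = rng.integers(2, 10, size=2)
            y0 = rng.integers(0, 8, n0) + 1  # keep group means positive
            y1 = rng.integers(0, 8, n1) + 1
            y = np.concatenate([y0, y1]).astype(float)
            X = np.column_stack(
                [np.ones(n0 + n1), np.r_[np.zeros(n0), np.ones(n1)]]
            )
            fit = fit_poisson(y, X)
            assert math.exp(fit.beta[1]) == pytest.approx(
                y1.mean() / y0.mean(), abs=1e-8
            )

    def test_null_effect_recovery(self):
        rng = np.random.default_rng(5)
        n = 5000
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        y = rng.poisson(3.0, n)
        fit = fit_poisson(y, X)
        assert math.exp(fit.beta[1]) == pytest.approx(1.0, abs=0.1)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(ValueError, match="rank"):
            fit_poisson(TOY_Y, X)

    def test_separation_marks_nonconvergence(self):
        """A covariate level with all-zero counts drives β → −∞; the
        separation guard reports converged=False."""
        y = np.array([0.0, 0.0, 0.0, 4.0, 5.0, 6.0])
        X = np.column_stack([np.ones(6), np.r_[np.ones(3), np.zeros(3)]])
        fit = fit_poisson(y, X)
        assert not fit.converged


class TestMultiResponse:
    @pytest.fixture()
    def cohort(self):
        rng = np.random.default_rng(2)
        n = 120
        df = pd.DataFrame(
            {
                "cT": rng.integers(0, 2, n),
                "cN": rng.integers(0, 2, n),
            }
        )
        for ph in PHENOTYPES:
            df[ph] = rng.poisson(np.exp(0.2 + 0.6 * df["cN"]))
        return df

    def test_joint_loglik_is_sum_and_aic_identity(self, cohort):
        fit = fit_multiresponse(cohort, DesignSpec(predictors=("cT", "cN")))
        assert fit.loglik == pytest.approx(
            sum(f.loglik for f in fit.per_response.values())
        )
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
        assert fit.k == 3 * 3  # three responses × (intercept + 2 predictors)

    def test_null_spec_additivity(self, cohort):
        fit = fit_multiresponse(cohort, DesignSpec(predictors=()))
        expected = sum(
            fit_poisson(round_counts(cohort[ph].to_numpy()),
                        np.ones((len(cohort), 1))).loglik
            for ph in PHENOTYPES
        )
        assert fit.loglik == pytest.approx(expected, abs=1e-8)

    def test_adding_predictor_never_decreases_loglik(self, cohort):
        ll0 = fit_multiresponse(cohort, DesignSpec(predictors=("cN",))).loglik
        ll1 = fit_multiresponse(cohort, DesignSpec(predictors=("cN", "cT"))).loglik
        assert ll1 >= ll0 - 1e-8

    def test_irr_ci_ordering_and_fractional_counts(self, cohort):
        cohort = cohort.copy()
        cohort["eCTC"] = cohort["eCTC"] + 0.4  # extrapolated fractional counts
        fit = fit_multiresponse(cohort, DesignSpec(predictors=("cN",)))
        for est in irr_table(fit):
            assert est.ci_low < est.irr < est.ci_high
            assert est.irr > 0
            assert 0 <= est.p_value <= 1


class TestEnumerate:
    def test_four_candidates_give_sixteen_models(self):
        specs = enumerate_models(["cT", "cN", "grade", "histology"])
        assert len(specs) == 16
        assert specs[0].is_null
        assert len({s.predictors for s in specs}) == 16

    def test_zero_candidates_give_null_model(self):
        specs = enumerate_models([])
        assert len(specs) == 1 and specs[0].is_null

    def test_exclusion_pair_flagging(self):
        specs = enumerate_models(
            ["cT", "cN", "grade", "histology"], exclusions=[("grade", "cN")]
        )
        for s in specs:
            both = {"grade", "cN"} <= set(s.predictors)
            assert s.rule_flagged == both
        assert sum(s.rule_flagged for s in specs) == 4  # 2^(4-2) supersets

    def test_duplicate_candidates_rejected(self):
        with pytest.raises(ValueError):
            enumerate_models(["cT", "cT"])


def brute_force_loo(data, predictors):
    """Independent leave-one-out CV oracle built on statsmodels."""
    n = len(data)
    X, _ = build_design(data, predictors)
    rmses, logliks, aics = [], [], []
    for i in range(n):
        tr = np.arange(n) != i
        sq, ll_te, ll_tr, k = 0.0, 0.0, 0.0, 0
        for ph in PHENOTYPES:
            y = round_counts(data[ph].to_numpy())
            res = sm.GLM(y[tr], X[tr], family=sm.families.Poisson()).fit()
            mu = np.exp(X[~tr] @ res.params)
            sq += float(np.sum((mu - y[~tr]) ** 2))
            ll_te += poisson_loglik(y[~tr], mu)
            ll_tr += res.llf
            k += X.shape[1]
        rmses.append(math.sqrt(sq / 3))
        logliks.append(ll_te)
        aics.append(2 * k - 2 * ll_tr)
    return np.mean(rmses), np.mean(logliks), np.mean(aics)


class TestCrossval:
    @pytest.fixture()
    def toy_cohort(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame({"x": [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]})
        for ph in PHENOTYPES:
            df[ph] = rng.poisson(np.exp(0.5 + 0.4 * df["x"]))
        return df

    def test_leave_one_out_matches_brute_force(self, toy_cohort):
        cv = crossval_model(
            toy_cohort, DesignSpec(predictors=("x",)), k=10, reps=1, seed=0
        )
        rmse, ll, aic = brute_force_loo(toy_cohort, ("x",))
        assert cv.avg_rmse == pytest.approx(rmse, abs=1e-6)
        assert cv.avg_loglik == pytest.approx(ll, abs=1e-6)
        assert cv.avg_aic == pytest.approx(aic, abs=1e-6)
        assert not cv.excluded

    def test_determinism_under_fixed_seed(self, toy_cohort):
        a = crossval_model(toy_cohort, DesignSpec(predictors=("x",)),
                           k=5, reps=3, seed=11)
        b = crossval_model(toy_cohort, DesignSpec(predictors=("x",)),
                           k=5, reps=3, seed=11)
        assert (a.avg_rmse, a.avg_loglik, a.avg_aic) == (
            b.avg_rmse, b.avg_loglik, b.avg_aic
        )

    def test_quasi_separation_leads_to_exclusion(self):
        """A covariate level with all-zero counts in one response makes CV
        fold fits fail to converge, excluding the model."""
        rng = np.random.default_rng(4)
        n = 40
        df = pd.DataFrame({"sep": np.r_[np.ones(8), np.zeros(n - 8)].astype(int)})
        for ph in PHENOTYPES:
            df[ph] = rng.poisson(2.0, n)
        df.loc[df["sep"] == 1, "eCTC"] = 0
        cv = crossval_model(df, DesignSpec(predictors=("sep",)), k=5, reps=2, seed=0)
        assert cv.excluded and cv.n_failed_fits > 0


class TestSelect:
    def _cv(self, rmse, ll, aic, excluded=False):
        return CvMetrics(avg_loglik=ll, avg_aic=aic, avg_rmse=rmse,
                         n_failed_fits=0, excluded=excluded)

    def test_single_candidate_wins(self):
        spec = DesignSpec(predictors=("a",))
        res = select_best([(spec, self._cv(1.0, -10, 25))])
        assert res.best == spec

    def test_rmse_first_ordering(self):
        """When the three criteria disagree, avg.RMSE decides."""
        s1, s2 = DesignSpec(predictors=("a",)), DesignSpec(predictors=("b",))
        res = select_best(
            [(s1, self._cv(2.0, -5, 10)), (s2, self._cv(1.0, -50, 200))]
        )
        assert res.best == s2

    def test_excluded_models_do_not_compete(self):
        s1, s2 = DesignSpec(predictors=("a",)), DesignSpec(predictors=("b",))
        res = select_best(
            [(s1, self._cv(0.5, -5, 10, excluded=True)), (s2, self._cv(1.0, -9, 20))]
        )
        assert res.best == s2
        assert len(res.non_competing) == 1

    def test_all_excluded_raises(self):
        s1 = DesignSpec(predictors=("a",))
        with pytest.raises(ValueError):
            select_best([(s1, self._cv(0.5, -5, 10, excluded=True))])


class TestNagelkerke:
    def test_zero_when_full_equals_null(self):
        assert nagelkerke_r2(-12.3, -12.3, 50) == 0.0

    def test_toy_hand_computed(self):
        """Evaluated with the closed-form log-likelihoods of the 5-count
        toy dataset, the implementation matches independent arithmetic."""
        mu_full = np.array([2.0, 2, 2, 5, 5])  # saturated two-group means
        mu_null = np.full(5, TOY_Y.mean())
        ll_full = toy_loglik(TOY_Y, mu_full)
        ll_null = toy_loglik(TOY_Y, mu_null)
        expected = (1 - math.exp((2 / 5) * (ll_null - ll_full))) / (
            1 - math.exp((2 / 5) * ll_null)
        )
        assert nagelkerke_r2(ll_full, ll_null, 5) == pytest.approx(expected, abs=1e-10)
        # and the fitted logliks reproduce the closed-form ones
        fit_full = fit_poisson(TOY_Y, TOY_X)
        fit_null = fit_poisson(TOY_Y, np.ones((5, 1)))
        assert nagelkerke_r2(fit_full.loglik, fit_null.loglik, 5) == pytest.approx(
            expected, abs=1e-8
        )

    def test_bounded_and_monotone(self):
        rng = np.random.default_rng(8)
        ll_null = -80.0
        previous = -0.1
        for ll_full in np.linspace(-80, -20, 10):
            r2 = nagelkerke_r2(ll_full, ll_null, 40)
            assert 0 <= r2 < 1
            assert r2 >= previous
            previous = r2

    def test_warns_when_full_below_null(self):
        with pytest.warns(UserWarning):
            nagelkerke_r2(-20.0, -10.0, 30)


class TestPartialR2:
    @pytest.fixture()
    def cohort(self):
        rng = np.random.default_rng(17)
        n = 400
        df = pd.DataFrame(
            {"s": rng.integers(0, 2, n), "noise": rng.integers(0, 2, n)}
        )
        for ph in PHENOTYPES:
            df[ph] = rng.poisson(np.exp(0.3 + 0.9 * df["s"]))
        return df

    def test_single_predictor_partial_equals_overall(self, cohort):
        dec = partial_r2(cohort, DesignSpec(predictors=("s",)))
        for ph in PHENOTYPES:
            assert dec.partial_r2[(ph, "s")] == pytest.approx(
                dec.per_response_r2[ph], abs=1e-10
            )

    def test_null_predictor_contributes_nothing(self, cohort):
        dec = partial_r2(cohort, DesignSpec(predictors=("s", "noise")))
        for ph in PHENOTYPES:
            assert abs(dec.partial_r2[(ph, "noise")]) < 0.02
            assert dec.partial_r2[(ph, "s")] > 0.05
        assert 0 <= dec.overall_r2 < 1

    def test_requires_a_predictor(self, cohort):
        with pytest.raises(ValueError):
            partial_r2(cohort, DesignSpec(predictors=()))
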