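import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import melanoprs as m
from melanoprs.modeling import ModelingError, SeparationError, build_design


def _binary_cohort(a, b, c, d):
    """Exposed/unexposed cases (a, b) and controls (c, d)."""
    y = np.r_[np.ones(a + b), np.zeros(c + d)].astype(int)
    x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    return pd.DataFrame({"status": y, "expo": x})


class TestFitLogistic:
    def test_intercept_only_fits_case_fraction(self):
        data = pd.DataFrame({"status": [1] * 30 + [0] * 70})
        fit = m.fit_logistic(data, m.ModelSpec(forced_terms=()))
        np.testing.assert_allclose(fit.fitted_prob, 0.3, atol=1e-8)

    def test_two_by_two_cross_product_oracle(self):
        # unadjusted tertile-3 vs tertile-1 counts: OR = (317*152)/(103*135)
        data = _binary_cohort(317, 103, 135, 152)
        fit = m.fit_logistic(
            data, m.ModelSpec(forced_terms=(), candidate_terms=("expo",))
        )
        assert np.exp(fit.coef("expo")) == pytest.approx(317 * 152 / (103 * 135), rel=1e-5)

    def test_matches_direct_likelihood_maximisation(self):
        rng = np.random.default_rng(5)
        n = 400
        x1 = rng.standard_normal(n)
        x2 = rng.integers(0, 2, n).astype(float)
        eta = -0.5 + 0.8 * x1 - 0.6 * x2
        y = (rng.random(n) < expit(eta)).astype(int)
        data = pd.DataFrame({"status": y, "x1": x1, "x2": x2})
        fit = m.fit_logistic(
            data, m.ModelSpec(forced_terms=(), candidate_terms=("x1", "x2"))
        )
        X = np.c_[np.ones(n), x1, x2]

        def negll(beta):
            lp = X @ beta
            return -np.sum(y * lp - np.logaddexp(0.0, lp))

        direct = minimize(negll, np.zeros(3), method="BFGS", tol=1e-12).x
        np.testing.assert_allclose(fit.params.to_numpy(), direct, atol=1e-6)

    def test_adjusted_or_collapses_when_covariate_independent(self):
        rng = np.random.default_rng(9)
        n = 20_000
        x = rng.integers(0, 2, n).astype(float)
        z = rng.standard_normal(n)  # independent of x
        y = (rng.random(n) < expit(-1.0 + 0.7 * x + 0.5 * z)).astype(int)
        data = pd.DataFrame({"status": y, "x": x, "z": z})
        crude = m.fit_logistic(
            data, m.ModelSpec(forced_terms=(), candidate_terms=("x",))
        ).coef("x")
        adjusted = m.fit_logistic(
            data, m.ModelSpec(forced_terms=(), candidate_terms=("x", "z"))
        ).coef("x")
        # logistic ORs are not exactly collapsible; agreement is approximate
        assert adjusted == pytest.approx(crude, abs=0.1)

    def test_fitted_probs_average_to_case_fraction(self, study_cohort):
        spec = m.ModelSpec(candidate_terms=("hair_color", "nevus_density"))
        fit = m.fit_logistic(study_cohort, spec)
        assert fit.fitted_prob.mean() == pytest.approx(
            study_cohort["status"].mean(), abs=1e-8
        )
        # covariance symmetric PSD
        cov = fit.cov.to_numpy()
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-10)

    def test_singular_design_names_columns(self):
        data = pd.DataFrame({
            "status": [0, 1] * 20,
            "x1": np.arange(40.0),
            "x2": 2.0 * np.arange(40.0),
        })
        with pytest.raises(ModelingError, match="x2"):
            m.fit_logistic(
                data, m.ModelSpec(forced_terms=(), candidate_terms=("x1", "x2"))
            )

    def test_perfect_separation_is_diagnosed(self):
        data = pd.DataFrame({
            "status": [0] * 20 + [1] * 20,
            "x": np.r_[np.zeros(20), np.ones(20)],
        })
        with pytest.raises(SeparationError):
            m.fit_logistic(
                data, m.ModelSpec(forced_terms=(), candidate_terms=("x",))
            )


class TestFixedWeightModel:
    def test_zero_offset_equals_plain_fit(self, study_cohort):
        spec = m.ModelSpec()
        zero = pd.Series(np.zeros(len(study_cohort)))
        via_offset = m.fixed_weight_model(study_cohort, [zero], spec)
        plain = m.fit_logistic(study_cohort, spec)
        np.testing.assert_allclose(
            via_offset.params.to_numpy(), plain.params.to_numpy(), atol=1e-8
        )

    def test_informative_offset_raises_loglik(self, study_cohort, default_man):
        spec = m.ModelSpec()
        prs = m.polygenic_score(study_cohort, default_man)
        base = m.fit_logistic(study_cohort, spec)
        with_score = m.fixed_weight_model(study_cohort, [prs], spec)
        assert with_score.loglik > base.loglik

    def test_true_linear_predictor_offset_has_unit_slope(self):
        rng = np.random.default_rng(3)
        n = 4_000
        eta = rng.standard_normal(n)
        y = (rng.random(n) < expit(-1.0 + eta)).astype(int)
        data = pd.DataFrame({"status": y, "eta": eta})
        # refit with the true predictor as a free covariate: slope ~ 1
        fit = m.fit_logistic(
            data, m.ModelSpec(forced_terms=(), candidate_terms=("eta",))
        )
        lo, hi = fit.wald_ci("eta")
        assert lo < 1.0 < hi


class TestBackwardSelect:
    def _null_data(self, seed, n=600, k=4):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame({
            "status": rng.integers(0, 2, n),
            "age": rng.uniform(18, 45, n),
        })
        for j in range(k):
            data[f"x{j}"] = rng.standard_normal(n)
        return data

    def test_forced_terms_survive_even_when_null(self):
        data = self._null_data(1)
        spec = m.ModelSpec(
            forced_terms=("age",), candidate_terms=("x0", "x1", "x2", "x3")
        )
        fit, trace = m.backward_select(data, spec)
        assert "age" in fit.term_columns

    def test_retained_candidates_all_below_threshold(self):
        data = self._null_data(2)
        spec = m.ModelSpec(
            forced_terms=("age",), candidate_terms=("x0", "x1", "x2", "x3")
        )
        fit, trace = m.backward_select(data, spec, p_retain=0.20)
        removed = {t["term"] for t in trace}
        kept = set(fit.term_columns) - {"age"}
        assert removed | kept == {"x0", "x1", "x2", "x3"}
        for t in trace:
            assert t["p"] >= 0.20

    def test_p_retain_limits(self):
        data = self._null_data(3)
        spec = m.ModelSpec(
            forced_terms=("age",), candidate_terms=("x0", "x1", "x2", "x3")
        )
        full, trace = m.backward_select(data, spec, p_retain=1.0 + 1e-9)
        assert set(full.term_columns) == {"age", "x0", "x1", "x2", "x3"}
        assert trace == []
        forced_only, _ = m.backward_select(data, spec, p_retain=1e-300)
        assert set(forced_only.term_columns) == {"age"}

    def test_strong_candidate_retained(self):
        rng = np.random.default_rng(17)
        n = 2_000
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < expit(-0.5 + np.log(3.0) * x)).astype(int)
        data = pd.DataFrame({
            "status": y, "x": x, "noise": rng.standard_normal(n)
        })
        fit, _ = m.backward_select(
            data, m.ModelSpec(forced_terms=(), candidate_terms=("x", "noise"))
        )
        assert "x" in fit.term_columns

    def test_multilevel_factor_tested_jointly(self, study_cohort):
        spec = m.ModelSpec(
            forced_terms=("age",),
            candidate_terms=("hair_color", "dose_R151C"),
        )
        fit, trace = m.backward_select(study_cohort, spec)
        # hair_color either fully present or fully absent
        if "hair_color" in fit.term_columns:
            assert len(fit.term_columns["hair_color"]) == 3


class TestCategoryOr:
    def test_tertile_or_matches_cross_product(self):
        # printed tertile counts (103,152)/(158,170)/(317,135) encoded as three
        # tied score values (the printed groups are not equal thirds of one
        # study because the cutpoints were pooled); ties keep each group in
        # its own category, and the unadjusted tertile-3 vs tertile-1 OR must
        # equal the cross product (317*152)/(103*135)
        parts = [(103, 152), (158, 170), (317, 135)]
        score, status = [], []
        for v, (cases, ctrls) in enumerate(parts):
            score += [float(v)] * (cases + ctrls)
            status += [1] * cases + [0] * ctrls
        data = pd.DataFrame({"status": status, "score": score})
        res = m.category_or(
            data["score"], data, n_categories=3,
            spec=m.ModelSpec(forced_terms=()), cutpoint_source="pooled",
        )
        row3 = res.table.iloc[2]
        assert (row3["n_case"], row3["n_control"]) == (317, 135)
        assert row3["or"] == pytest.approx(317 * 152 / (103 * 135), rel=1e-5)
        assert res.table.iloc[0]["or"] == 1.0
        assert res.trend_p < 1e-10

    def test_null_score_ors_near_one(self, null_cohort, default_man):
        prs = m.polygenic_score(null_cohort, default_man)
        res = m.category_or(prs, null_cohort, n_categories=3)
        for _, row in res.table.iloc[1:].iterrows():
            assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_two_categories_match_dichotomised_fit(self, study_cohort, default_man):
        prs = m.polygenic_score(study_cohort, default_man)
        res = m.category_or(
            prs, study_cohort, n_categories=2, spec=m.ModelSpec(forced_terms=())
        )
        cut = res.cutpoints[0]
        data = study_cohort.copy()
        data["hi"] = (prs >= cut).astype(float)
        fit = m.fit_logistic(
            data, m.ModelSpec(forced_terms=(), candidate_terms=("hi",))
        )
        assert res.table.iloc[1]["or"] == pytest.approx(
            np.exp(fit.coef("hi")), rel=1e-8
        )

    def test_counts_partition_cohort(self, study_cohort, default_man):
        prs = m.polygenic_score(study_cohort, default_man)
        res = m.category_or(prs, study_cohort, n_categories=10)
        assert res.table["n_case"].sum() == study_cohort["status"].sum()
        assert res.table["n_control"].sum() == (1 - study_cohort["status"]).sum()

    def test_degenerate_score_raises(self, study_cohort):
        const = pd.Series(np.ones(len(study_cohort)))
        with pytest.raises(ModelingError, match="empty"):
            m.category_or(const, study_cohort, n_categories=3)


class TestKfoldCv:
    def test_partition_contract(self, study_cohort):
        spec = m.ModelSpec(candidate_terms=("hair_color", "nevus_density"))
        oof, res = m.kfold_cv(study_cohort, spec, k=5, seed=1)
        assert len(oof) == len(study_cohort)
        assert np.all((oof > 0) & (oof < 1))

    def test_loo_is_seed_free(self):
        rng = np.random.default_rng(2)
        n = 60
        data = pd.DataFrame({
            "status": rng.integers(0, 2, n), "x": rng.standard_normal(n)
        })
        spec = m.ModelSpec(forced_terms=(), candidate_terms=("x",))
        oof1, _ = m.kfold_cv(data, spec, k=n, seed=1)
        oof2, _ = m.kfold_cv(data, spec, k=n, seed=99)
        np.testing.assert_array_equal(oof1, oof2)

    def test_overfitting_corrected_under_null(self):
        rng = np.random.default_rng(8)
        n, k = 400, 30
        data = pd.DataFrame({"status": np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)})
        for j in range(k):
            data[f"x{j}"] = rng.standard_normal(n)
        spec = m.ModelSpec(
            forced_terms=(), candidate_terms=tuple(f"x{j}" for j in range(k))
        )
        fit = m.fit_logistic(data, spec)
        train_auc = m.auc(fit.fitted_prob, data["status"]).auc
        _, cv = m.kfold_cv(data, spec, k=10, seed=3)
        assert train_auc > 0.5
        assert abs(cv.auc - 0.5) < 3 * cv.se + 0.02
        assert train_auc > cv.auc
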