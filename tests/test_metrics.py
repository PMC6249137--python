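import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import melanoprs as m
from melanoprs.metrics import MetricsError


def pair_count_auc(pred, y):
    """Exhaustive mean over case-control pairs: 1[case > ctrl] + 0.5 ties."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=int)
    cases = pred[y == 1][:, None]
    ctrls = pred[y == 0][None, :]
    return float(np.mean((cases > ctrls) + 0.5 * (cases == ctrls)))


class TestAuc:
    def test_perfect_separation(self):
        r = m.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_hand_enumeration(self):
        r = m.auc([0.9, 0.4, 0.4, 0.1], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.875)

    def test_all_ties(self):
        assert m.auc([0.3] * 10, [1] * 4 + [0] * 6).auc == 0.5

    def test_single_class_raises(self):
        with pytest.raises(MetricsError):
            m.auc([0.1, 0.2], [1, 1])

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(1)
        pred = rng.random(100)
        y = rng.integers(0, 2, 100)
        r = m.auc(pred, y)
        assert r.ci95[0] <= r.auc <= r.ci95[1]
        assert 0.0 <= r.ci95[0] and r.ci95[1] <= 1.0

    def test_matches_sklearn_point_estimate(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        pred = rng.random(300)
        y = rng.integers(0, 2, 300)
        assert m.auc(pred, y).auc == pytest.approx(
            roc_auc_score(y, pred), abs=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        pred = rng.choice(rng.random(max(2, n // 3)), size=n)  # force ties
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if y.sum() in (0, n):
            return
        assert m.auc(pred, y).auc == pytest.approx(
            pair_count_auc(pred, y), abs=1e-12
        )


class TestCompareAuc:
    def test_identical_models(self):
        pred = np.linspace(0.1, 0.9, 30)
        y = (np.arange(30) % 2 == 0).astype(int)
        r = m.compare_auc(pred, pred, y)
        assert r.delta_auc == 0.0
        assert r.p == 1.0

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        pred = rng.random(80)
        y = rng.integers(0, 2, 80)
        r = m.compare_auc(pred, expit(5 * pred - 2), y)
        assert r.delta_auc == pytest.approx(0.0, abs=1e-12)

    def test_variance_against_bootstrap(self):
        # paired placement variance of dAUC vs a resampling estimate
        rng = np.random.default_rng(11)
        n = 200
        signal = rng.standard_normal(n)
        y = (rng.random(n) < expit(signal)).astype(int)
        pred_base = expit(signal + rng.standard_normal(n))
        pred_new = expit(signal + 0.7 * rng.standard_normal(n))

        a_b, v10_b, v01_b = m.metrics._placements(pred_base, y)
        deltas = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            yy = y[idx]
            if yy.sum() in (0, n):
                continue
            d = (
                m.metrics._placements(pred_new[idx], yy)[0]
                - m.metrics._placements(pred_base[idx], yy)[0]
            )
            deltas.append(d)
        boot_var = np.var(deltas, ddof=1)
        r = m.compare_auc(pred_base, pred_new, y)
        analytic_var = r.delta_auc**2 / r.chi2 if r.chi2 > 0 else 0.0
        assert analytic_var == pytest.approx(boot_var, rel=0.15)

    def test_null_p_value_uniformity(self):
        # two equally informative independent half-signals: P ~ Uniform(0,1)
        from scipy.stats import kstest

        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(500):
            n = 150
            s1 = rng.standard_normal(n)
            s2 = rng.standard_normal(n)
            y = (rng.random(n) < expit(0.7 * (s1 + s2))).astype(int)
            if y.sum() in (0, n):
                continue
            pvals.append(m.compare_auc(expit(s1), expit(s2), y).p)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestContinuousNri:
    def test_hand_enumeration(self):
        p_base = np.array([0.5, 0.5, 0.5, 0.5, 0.5])
        p_new = p_base + np.array([0.1, 0.2, -0.1, -0.1, 0.05])
        y = np.array([1, 1, 1, 0, 0])
        r = m.continuous_nri(p_base, p_new, y)
        assert r.event_nri == pytest.approx(1 / 3)
        assert r.nonevent_nri == pytest.approx(0.0)
        assert r.total_nri == pytest.approx(1 / 3)

    def test_no_reclassification(self):
        pred = np.linspace(0.1, 0.9, 20)
        y = (np.arange(20) % 2).astype(int)
        r = m.continuous_nri(pred, pred, y)
        assert r.event_nri == r.nonevent_nri == r.total_nri == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_identities_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 120))
        pb, pn = rng.random(n), rng.random(n)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            return
        r = m.continuous_nri(pb, pn, y)
        assert r.total_nri == pytest.approx(r.event_nri + r.nonevent_nri, abs=1e-12)
        assert -1.0 <= r.event_nri <= 1.0
        assert -1.0 <= r.nonevent_nri <= 1.0
        assert -2.0 <= r.total_nri <= 2.0
        back = m.continuous_nri(pn, pb, y)
        assert back.event_nri == pytest.approx(-r.event_nri, abs=1e-12)
        assert back.nonevent_nri == pytest.approx(-r.nonevent_nri, abs=1e-12)


class TestOpera:
    def _data(self, seed, n=3000, beta=0.5):
        rng = np.random.default_rng(seed)
        score = rng.standard_normal(n)
        age = rng.uniform(18, 60, n)
        sex = rng.choice(["female", "male"], n)
        y = (rng.random(n) < expit(-1.0 + beta * score)).astype(int)
        return pd.DataFrame({"status": y, "age": age, "sex": sex}), score

    def test_null_score_or_near_one(self):
        data, score = self._data(2, n=5000, beta=0.0)
        r = m.opera(score, data)
        assert r.ci95[0] < 1.0 < r.ci95[1]
        assert r.or_per_adj_sd == pytest.approx(1.0, abs=0.1)

    def test_no_covariates_equals_control_sd_scaling(self):
        data, score = self._data(3)
        r = m.opera(score, data, adj_covars=())
        ctrl_sd = np.std(score[data["status"] == 0], ddof=1)
        fit = m.fit_logistic(
            data.assign(s=score / ctrl_sd),
            m.ModelSpec(forced_terms=(), candidate_terms=("s",)),
        )
        assert r.or_per_adj_sd == pytest.approx(np.exp(fit.coef("s")), rel=1e-8)
        assert r.adj_sd == pytest.approx(ctrl_sd, rel=1e-12)

    def test_affine_rescaling_invariance(self):
        data, score = self._data(4)
        r1 = m.opera(score, data)
        r2 = m.opera(37.5 * score, data)
        assert r2.or_per_adj_sd == pytest.approx(r1.or_per_adj_sd, rel=1e-8)

    def test_degenerate_score_raises(self):
        data, _ = self._data(5, n=200)
        with pytest.raises(MetricsError, match="degenerate"):
            m.opera(np.zeros(len(data)), data, adj_covars=())


class TestHosmerLemeshow:
    def test_perfect_calibration_statistic_zero(self):
        # 10 groups of 20 where observed case counts equal expected exactly
        pred, y = [], []
        for k in range(10):
            p = (k + 1) / 20.0  # 0.05 .. 0.50
            n_g, cases = 20, int(round(20 * ((k + 1) / 20.0)))
            pred += [p] * n_g
            y += [1] * cases + [0] * (n_g - cases)
        r = m.hosmer_lemeshow(np.array(pred), np.array(y), g=10)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_two_group_hand_arithmetic(self):
        pred = np.r_[np.full(50, 0.16), np.full(50, 0.44)]
        y = np.r_[np.ones(10), np.zeros(40), np.ones(20), np.zeros(30)].astype(int)
        r = m.hosmer_lemeshow(pred, y, g=2)
        assert r.statistic == pytest.approx(0.91991, abs=1e-4)
        assert r.df == 0  # degenerate: no reference distribution

    def test_ordering_invariance(self):
        rng = np.random.default_rng(6)
        pred = rng.random(300)
        y = (rng.random(300) < pred).astype(int)
        r1 = m.hosmer_lemeshow(pred, y)
        perm = rng.permutation(300)
        r2 = m.hosmer_lemeshow(pred[perm], y[perm])
        assert r2.statistic == pytest.approx(r1.statistic, abs=1e-10)

    def test_extreme_group_raises(self):
        pred = np.r_[np.zeros(30), np.full(30, 0.5)]
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        with pytest.raises(MetricsError, match="group"):
            m.hosmer_lemeshow(pred, y, g=2)
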