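"""Discrimination, reclassification, calibration and per-SD association.

Implements the evaluation statistics for comparing risk models on
case-control data:

* **AUC** by the Mann-Whitney estimator with a correlated-ROC
  (placement-value) variance, so the single-model confidence interval and
  the paired model comparison share machinery;
* **paired AUC comparison**: the variance of the AUC difference is computed
  from per-subject placement values on the same sample, and the squared
  standardised difference is referred to chi-square with 1 df;
* **category-free continuous NRI** with its case (sensitivity) and control
  (specificity) components, ties counting to neither direction, and the
  binomial-difference asymptotic variance for the confidence intervals;
* **OPERA** — odds ratio per adjusted standard deviation: the score is
  scaled by the SD of its covariate-adjusted residuals among controls
  (controls standing in for the reference population), then entered in an
  adjusted logistic model;
* **Hosmer-Lemeshow** calibration test over equal-size groups of predicted
  risk with chi-square on g - 2 df.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "MetricsError",
    "AucResult",
    "AucComparison",
    "NriResult",
    "OperaResult",
    "HlResult",
    "auc",
    "compare_auc",
    "continuous_nri",
    "opera",
    "hosmer_lemeshow",
]

_Z95 = float(norm.ppf(0.975))


class MetricsError(ValueError):
    """An evaluation statistic could not be computed."""


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if y.ndim != 1:
        raise MetricsError("status vector must be one-dimensional")
    if not np.all(np.isin(y, [0, 1])):
        raise MetricsError("status must be coded 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise MetricsError("both cases and controls must be present")
    return y


def _placements(pred: np.ndarray, y: np.ndarray):
    """Mann-Whitney AUC and per-subject placement values (midrank method)."""
    x, z = pred[y == 1], pred[y == 0]
    m, n = len(x), len(z)
    combined = np.concatenate([x, z])
    r_all = rankdata(combined)
    v10 = (r_all[:m] - rankdata(x)) / n
    v01 = 1.0 - (r_all[m:] - rankdata(z)) / m
    return float(v10.mean()), v10, v01


@dataclass(frozen=True)
class AucResult:
    """AUC with a placement-variance 95% confidence interval."""

    auc: float
    ci95: Tuple[float, float]
    n_case: int
    n_control: int
    se: float

    def to_dict(self) -> Dict:
        return {
            "auc": self.auc, "ci95": list(self.ci95), "se": self.se,
            "n_case": self.n_case, "n_control": self.n_control,
        }


@dataclass(frozen=True)
class AucComparison:
    """Paired correlated-ROC comparison of two models' AUCs."""

    auc_base: float
    auc_new: float
    delta_auc: float
    chi2: float
    p: float

    def to_dict(self) -> Dict:
        return {
            "auc_base": self.auc_base, "auc_new": self.auc_new,
            "delta_auc": self.delta_auc, "chi2": self.chi2, "p": self.p,
        }


@dataclass(frozen=True)
class NriResult:
    """Category-free continuous net reclassification improvement."""

    event_nri: float
    nonevent_nri: float
    total_nri: float
    event_ci95: Tuple[float, float]
    nonevent_ci95: Tuple[float, float]
    total_ci95: Tuple[float, float]

    def to_dict(self) -> Dict:
        return {
            "event_nri": self.event_nri, "event_ci95": list(self.event_ci95),
            "nonevent_nri": self.nonevent_nri,
            "nonevent_ci95": list(self.nonevent_ci95),
            "total_nri": self.total_nri, "total_ci95": list(self.total_ci95),
        }


@dataclass(frozen=True)
class OperaResult:
    """Odds ratio per adjusted standard deviation of a risk score."""

    or_per_adj_sd: float
    ci95: Tuple[float, float]
    adj_sd: float

    def to_dict(self) -> Dict:
        return {
            "or_per_adj_sd": self.or_per_adj_sd, "ci95": list(self.ci95),
            "adj_sd": self.adj_sd,
        }


@dataclass(frozen=True)
class HlResult:
    """Hosmer-Lemeshow goodness-of-fit test."""

    statistic: float
    df: int
    p: float
    table: pd.DataFrame

    def to_dict(self) -> Dict:
        return {
            "statistic": self.statistic, "df": self.df, "p": self.p,
            "table": self.table.to_dict(orient="records"),
        }


def auc(pred: Sequence[float], y: Sequence[int]) -> AucResult:
    """AUC (probability a case outranks a control), ties counting half.

    Equals the exhaustive mean over all case-control pairs of
    ``1[pred_case > pred_ctrl] + 0.5 * 1[equal]``; the CI uses the
    placement-value variance (case and control components).
    """
    pred = np.asarray(pred, dtype=float)
    y = _check_binary(np.asarray(y))
    if len(pred) != len(y):
        raise MetricsError("pred and y must have the same length")
    a, v10, v01 = _placements(pred, y)
    m, n = int(y.sum()), int(len(y) - y.sum())
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    se = float(np.sqrt(var))
    lo = max(0.0, a - _Z95 * se)
    hi = min(1.0, a + _Z95 * se)
    return AucResult(auc=a, ci95=(lo, hi), n_case=m, n_control=n, se=se)


def compare_auc(
    pred_base: Sequence[float], pred_new: Sequence[float], y: Sequence[int]
) -> AucComparison:
    """Paired test of the AUC difference on the same participants.

    The variance of the difference is estimated from the per-subject
    placement values of both models; ``chi2 = delta^2 / var`` is referred to
    chi-square with 1 df.
    """
    pb = np.asarray(pred_base, dtype=float)
    pn = np.asarray(pred_new, dtype=float)
    y = _check_binary(np.asarray(y))
    if len(pb) != len(y) or len(pn) != len(y):
        raise MetricsError("prediction vectors must match y in length")
    a_b, v10_b, v01_b = _placements(pb, y)
    a_n, v10_n, v01_n = _placements(pn, y)
    m, n = int(y.sum()), int(len(y) - y.sum())
    delta = a_n - a_b
    var = 0.0
    if m > 1:
        var += np.var(v10_n - v10_b, ddof=1) / m
    if n > 1:
        var += np.var(v01_n - v01_b, ddof=1) / n
    if var <= 0.0:
        stat = 0.0 if delta == 0.0 else np.inf
    else:
        stat = delta * delta / var
    p = float(chi2.sf(stat, 1))
    return AucComparison(
        auc_base=a_b, auc_new=a_n, delta_auc=float(delta),
        chi2=float(stat), p=p,
    )


def _nri_component(delta: np.ndarray, sign: float):
    """Net up-minus-down proportion and its asymptotic variance."""
    n = len(delta)
    p_up = float(np.mean(sign * delta > 0))
    p_down = float(np.mean(sign * delta < 0))
    nri = p_up - p_down
    var = (p_up + p_down - nri * nri) / n
    return nri, max(var, 0.0)


def continuous_nri(
    p_base: Sequence[float], p_new: Sequence[float], y: Sequence[int]
) -> NriResult:
    """Category-free continuous NRI with case/control decomposition.

    The event (sensitivity) component is the net proportion of cases whose
    predicted risk rises; the non-event (specificity) component is the net
    proportion of controls whose predicted risk falls. Ties count to
    neither direction. Component CIs use the binomial-difference asymptotic
    variance ``[p_up + p_down - (p_up - p_down)^2] / n_group``; the total's
    variance is the sum of the two independent components.
    """
    pb = np.asarray(p_base, dtype=float)
    pn = np.asarray(p_new, dtype=float)
    y = _check_binary(np.asarray(y))
    if len(pb) != len(y) or len(pn) != len(y):
        raise MetricsError("probability vectors must match y in length")
    delta = pn - pb
    ev, var_ev = _nri_component(delta[y == 1], sign=+1.0)
    ne, var_ne = _nri_component(delta[y == 0], sign=-1.0)
    total = ev + ne
    se_ev, se_ne = np.sqrt(var_ev), np.sqrt(var_ne)
    se_t = float(np.sqrt(var_ev + var_ne))
    return NriResult(
        event_nri=ev, nonevent_nri=ne, total_nri=total,
        event_ci95=(ev - _Z95 * se_ev, ev + _Z95 * se_ev),
        nonevent_ci95=(ne - _Z95 * se_ne, ne + _Z95 * se_ne),
        total_ci95=(total - _Z95 * se_t, total + _Z95 * se_t),
    )


def opera(
    score: Sequence[float],
    data: pd.DataFrame,
    adj_covars: Sequence[str] = ("age", "sex"),
    outcome: str = "status",
) -> OperaResult:
    """Odds ratio per adjusted standard deviation (OPERA).

    (1) The score is regressed on the adjustment covariates among controls
    only; (2) the adjusted SD is the sample SD of those control residuals;
    (3) the score divided by that SD enters an adjusted logistic model of
    case status, and the OR per adjusted SD is the exponentiated
    coefficient with its Wald 95% CI. With no covariates this reduces to
    the OR per control-sample SD of the raw score.
    """
    from .modeling import ModelSpec, build_design, fit_logistic

    s = np.asarray(score, dtype=float)
    y = _check_binary(data[outcome].to_numpy())
    if len(s) != len(data):
        raise MetricsError("score length does not match data")
    controls = data.loc[y == 0]
    s_ctrl = s[y == 0]
    if adj_covars:
        Xc, _ = build_design(controls, tuple(adj_covars))
        arr = Xc.to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(arr, s_ctrl, rcond=None)
        resid = s_ctrl - arr @ beta
    else:
        resid = s_ctrl - s_ctrl.mean()
    adj_sd = float(np.std(resid, ddof=1))
    if not adj_sd > 0:
        raise MetricsError(
            "adjusted SD of the score among controls is zero (degenerate score)"
        )
    work = data.copy()
    work["_score_per_sd"] = s / adj_sd
    spec = ModelSpec(outcome, tuple(adj_covars), ("_score_per_sd",))
    fit = fit_logistic(work, spec)
    b = fit.coef("_score_per_sd")
    lo, hi = fit.wald_ci("_score_per_sd")
    return OperaResult(
        or_per_adj_sd=float(np.exp(b)),
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        adj_sd=adj_sd,
    )


def hosmer_lemeshow(
    pred: Sequence[float], y: Sequence[int], g: int = 10
) -> HlResult:
    """Hosmer-Lemeshow chi-square calibration test.

    Participants are ranked by predicted risk (stable sort, so ties keep
    their input order) and split into ``g`` equal-size groups; the statistic
    sums ``(O - E)^2 / (E * (1 - E/n_g))`` over groups and is referred to
    chi-square with ``g - 2`` df.
    """
    pred = np.asarray(pred, dtype=float)
    y = _check_binary(np.asarray(y))
    if len(pred) != len(y):
        raise MetricsError("pred and y must have the same length")
    if g < 2:
        raise MetricsError("g must be at least 2")
    if len(y) < 2 * g:
        raise MetricsError(f"need at least 2*g = {2 * g} observations")
    order = np.argsort(pred, kind="stable")
    groups = np.array_split(order, g)
    rows, stat = [], 0.0
    for k, idx in enumerate(groups, start=1):
        n_g = len(idx)
        obs = float(y[idx].sum())
        exp = float(pred[idx].sum())
        if exp <= 0.0 or exp >= n_g:
            raise MetricsError(
                f"group {k} has expected count {exp} of {n_g}; use fewer groups"
            )
        stat += (obs - exp) ** 2 / (exp * (1.0 - exp / n_g))
        rows.append({
            "group": k, "n": n_g, "observed": obs, "expected": exp,
            "mean_pred": float(pred[idx].mean()),
        })
    df = g - 2
    p = float(chi2.sf(stat, df)) if df > 0 else float("nan")
    return HlResult(
        statistic=float(stat), df=df, p=p, table=pd.DataFrame(rows)
    )
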