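"""Logistic risk models for case-control data.

Covers the model-fitting machinery of the analysis: maximum-likelihood
logistic regression (via iteratively reweighted least squares), models in
which externally weighted risk scores enter as offsets with coefficient
pinned to 1 (preventing overfitting to the analysis sample), backward
elimination with forced design covariates, tertile/decile odds-ratio tables
with trend tests, and stratified k-fold cross-validation.

Categorical covariates are expanded to indicator columns against a
reference level (the first level of the factor's known ordering, else the
first sorted observed level); multi-level factors are tested jointly by
likelihood-ratio tests during selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2, norm

from .simulate import CATEGORY_LEVELS

__all__ = [
    "ModelingError",
    "SeparationError",
    "ModelSpec",
    "FittedModel",
    "CategoryOrTable",
    "build_design",
    "fit_logistic",
    "fixed_weight_model",
    "backward_select",
    "category_or",
    "kfold_cv",
    "DEMOGRAPHIC_TERMS",
]

_PROB_EPS = 1e-10

#: Forced demographic / study-design adjustment covariates.
DEMOGRAPHIC_TERMS = ("age", "sex", "center", "ancestry")


class ModelingError(ValueError):
    """A model could not be specified or fitted."""


class SeparationError(ModelingError):
    """The likelihood is degenerate: fitted probabilities reached 0 or 1."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a logistic model's terms.

    ``forced_terms`` are always present (demographics and design factors);
    ``candidate_terms`` are subject to selection. The two sets must be
    disjoint and the outcome binary.
    """

    outcome: str = "status"
    forced_terms: Tuple[str, ...] = DEMOGRAPHIC_TERMS
    candidate_terms: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.forced_terms) & set(self.candidate_terms)
        if overlap:
            raise ModelingError(
                f"terms both forced and candidate: {sorted(overlap)}"
            )

    @property
    def terms(self) -> Tuple[str, ...]:
        return tuple(self.forced_terms) + tuple(self.candidate_terms)


@dataclass
class FittedModel:
    """Result of a logistic fit.

    ``params``/``cov`` are labelled by design column; ``term_columns`` maps
    each model term to its design columns (one for numeric terms, level
    indicators for categorical terms); ``fitted_prob`` are in-sample
    predicted probabilities (including any offset).
    """

    params: pd.Series
    cov: pd.DataFrame
    fitted_prob: np.ndarray
    loglik: float
    converged: bool
    term_columns: Dict[str, List[str]]
    offset: Optional[np.ndarray] = None

    def coef(self, column: str) -> float:
        return float(self.params[column])

    def se(self, column: str) -> float:
        return float(np.sqrt(self.cov.loc[column, column]))

    def wald_ci(self, column: str, level: float = 0.95) -> Tuple[float, float]:
        z = norm.ppf(0.5 + level / 2.0)
        b, s = self.coef(column), self.se(column)
        return (b - z * s, b + z * s)

    def predict(self, X: pd.DataFrame, offset: Optional[np.ndarray] = None) -> np.ndarray:
        eta = X[self.params.index].to_numpy(dtype=float) @ self.params.to_numpy()
        if offset is not None:
            eta = eta + offset
        return expit(eta)

    def to_dict(self) -> Dict:
        """JSON-serialisable summary: coefficients, 95% CIs, fit statistics."""
        coefs = {}
        for col in self.params.index:
            lo, hi = self.wald_ci(col)
            coefs[col] = {
                "coef": self.coef(col), "se": self.se(col),
                "ci95": [lo, hi], "or": float(np.exp(self.coef(col))),
            }
        return {
            "coefficients": coefs,
            "loglik": self.loglik,
            "converged": self.converged,
            "n": int(len(self.fitted_prob)),
        }


def _reference_level(column: str, values: pd.Series) -> str:
    if column in CATEGORY_LEVELS:
        return CATEGORY_LEVELS[column][0]
    return sorted(values.astype(str).unique())[0]


def build_design(
    data: pd.DataFrame, terms: Sequence[str]
) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Expand model terms into a design matrix with an intercept.

    Numeric terms pass through; categorical terms become indicator columns
    ``term[level]`` for every non-reference level (a single-level factor
    contributes no columns). Returns the design matrix and the term-to-
    columns map.
    """
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    term_columns: Dict[str, List[str]] = {}
    for term in terms:
        if term not in data.columns:
            raise ModelingError(f"model term {term!r} not found in data")
        col = data[term]
        if pd.api.types.is_numeric_dtype(col) and term != "vacation_sun_q":
            X[term] = col.to_numpy(dtype=float)
            term_columns[term] = [term]
        else:
            values = col.astype(str)
            ref = _reference_level(term, values)
            levels = (
                [l for l in CATEGORY_LEVELS[term] if l in set(values)]
                if term in CATEGORY_LEVELS
                else sorted(values.unique())
            )
            cols = []
            for level in levels:
                if level == ref:
                    continue
                name = f"{term}[{level}]"
                X[name] = (values == level).astype(float).to_numpy()
                cols.append(name)
            term_columns[term] = cols
    return X, term_columns


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns incrementally
        bad, keep = [], []
        for j, name in enumerate(X.columns):
            trial = arr[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(name)
        raise ModelingError(
            f"singular design: columns {bad} are collinear with the others"
        )


def _fit_glm(
    y: np.ndarray, X: pd.DataFrame, offset: Optional[np.ndarray]
) -> sm.GLM:
    model = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset)
    return model.fit(maxiter=200, tol=1e-10)


def fit_logistic(
    data: pd.DataFrame,
    spec: ModelSpec,
    offset: Optional[np.ndarray] = None,
) -> FittedModel:
    """Maximum-likelihood logistic regression (IRLS) for a model spec.

    ``offset`` enters the linear predictor with coefficient fixed at 1.
    Raises :class:`SeparationError` on (quasi-)perfect separation and
    :class:`ModelingError` on a singular design, naming collinear columns.
    """
    if spec.outcome not in data.columns:
        raise ModelingError(f"outcome column {spec.outcome!r} not found")
    y = data[spec.outcome].to_numpy(dtype=float)
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])) or len(uniq) < 2:
        raise ModelingError(
            "outcome must be binary 0/1 with both classes present"
        )
    X, term_columns = build_design(data, spec.terms)
    _check_rank(X)
    try:
        res = _fit_glm(y, X, offset)
    except Exception as exc:  # statsmodels PerfectSeparation or numeric failure
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    prob = np.asarray(res.fittedvalues, dtype=float)
    if np.any(prob <= _PROB_EPS) or np.any(prob >= 1.0 - _PROB_EPS):
        raise SeparationError(
            "fitted probabilities reached 0/1: (quasi-)perfect separation"
        )
    return FittedModel(
        params=pd.Series(res.params, index=X.columns),
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        fitted_prob=prob,
        loglik=float(res.llf),
        converged=bool(res.converged),
        term_columns=term_columns,
        offset=None if offset is None else np.asarray(offset, dtype=float),
    )


def fixed_weight_model(
    data: pd.DataFrame,
    scores: Sequence[pd.Series],
    spec: Optional[ModelSpec] = None,
) -> FittedModel:
    """Logistic model with externally weighted score(s) as an offset.

    The supplied scores (already on the log-odds scale) enter the linear
    predictor with coefficient pinned to 1, while the spec's forced
    demographic terms (and intercept) are estimated freely. The fitted
    probabilities are the model's predicted risks for discrimination,
    reclassification and calibration analyses.
    """
    spec = spec or ModelSpec()
    if spec.candidate_terms:
        raise ModelingError(
            "fixed_weight_model estimates forced terms only; move candidate "
            "terms into a free-fit spec instead"
        )
    offset = np.zeros(len(data))
    for s in scores:
        if len(s) != len(data):
            raise ModelingError("score length does not match data")
        offset = offset + np.asarray(s, dtype=float)
    return fit_logistic(data, spec, offset=offset)


def _lr_test(full_ll: float, reduced_ll: float, df: int) -> float:
    stat = max(0.0, 2.0 * (full_ll - reduced_ll))
    return float(chi2.sf(stat, df)) if df > 0 else 1.0


def backward_select(
    data: pd.DataFrame,
    spec: ModelSpec,
    p_retain: float = 0.20,
    offset: Optional[np.ndarray] = None,
) -> Tuple[FittedModel, List[Dict]]:
    """Backward elimination keeping candidates with P < ``p_retain``.

    Forced terms are never dropped. At each step every remaining candidate
    is tested by a likelihood-ratio test (multi-level factors jointly); the
    candidate with the largest P >= ``p_retain`` is removed, ties broken in
    favour of the later position in the candidate list. The returned trace
    records each removal with its P-value.
    """
    remaining = list(spec.candidate_terms)
    trace: List[Dict] = []
    while True:
        full_spec = ModelSpec(spec.outcome, spec.forced_terms, tuple(remaining))
        full = fit_logistic(data, full_spec, offset=offset)
        if not remaining:
            return full, trace
        pvals = []
        for term in remaining:
            others = tuple(t for t in remaining if t != term)
            red_spec = ModelSpec(spec.outcome, spec.forced_terms, others)
            red = fit_logistic(data, red_spec, offset=offset)
            df = len(full.term_columns[term])
            pvals.append(_lr_test(full.loglik, red.loglik, df))
        worst_idx = max(
            range(len(remaining)), key=lambda i: (pvals[i], i)
        )
        if pvals[worst_idx] < p_retain:
            return full, trace
        dropped = remaining.pop(worst_idx)
        trace.append({"term": dropped, "p": pvals[worst_idx]})


@dataclass
class CategoryOrTable:
    """Per-category adjusted odds ratios for a quantile-cut score.

    ``table`` has one row per category: score range, case/control counts,
    OR with 95% CI (reference category OR = 1); ``trend_p`` is the Wald P
    for the ordinal category index entered as a single term.
    """

    table: pd.DataFrame
    trend_p: float
    cutpoints: np.ndarray

    def to_dict(self) -> Dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "trend_p": self.trend_p,
            "cutpoints": [float(c) for c in self.cutpoints],
        }


def assign_quantile_categories(
    score: np.ndarray, n_categories: int, reference: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Cut a score at quantiles of a reference sample into 1..k categories.

    Intervals are half-open ``[low, high)`` with the top interval closed;
    values exactly at a cutpoint go to the upper category.
    """
    ref = score if reference is None else reference
    qs = np.arange(1, n_categories) / n_categories
    cuts = np.quantile(ref, qs)
    cat = 1 + np.searchsorted(cuts, score, side="right")
    counts = np.bincount(cat, minlength=n_categories + 1)[1:]
    if np.any(counts == 0):
        empty = int(np.argmin(counts)) + 1
        raise ModelingError(
            f"quantile category {empty} of {n_categories} is empty "
            f"(ties at cutpoints {cuts.tolist()})"
        )
    return cat, cuts


def category_or(
    score: pd.Series,
    data: pd.DataFrame,
    n_categories: int = 3,
    spec: Optional[ModelSpec] = None,
    cutpoint_source: str = "per-study",
    study_col: str = "study",
) -> CategoryOrTable:
    """Adjusted ORs by score quantile category, with a trend test.

    ``cutpoint_source='per-study'`` computes cutpoints within each level of
    ``study_col`` when that column exists (each study contributes its own
    equal thirds/tenths); ``'pooled'`` uses quantiles of the combined
    sample. The lowest category is the reference; remaining categories
    enter an adjusted logistic fit as indicators.
    """
    spec = spec or ModelSpec()
    s = np.asarray(score, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ModelingError("score contains non-finite values")
    if cutpoint_source not in ("per-study", "pooled"):
        raise ModelingError(
            f"cutpoint_source must be 'per-study' or 'pooled', got "
            f"{cutpoint_source!r}"
        )
    if cutpoint_source == "per-study" and study_col in data.columns:
        cat = np.zeros(len(s), dtype=int)
        cuts = None
        for _, idx in data.groupby(study_col).groups.items():
            pos = data.index.get_indexer(idx)
            cat[pos], cuts = assign_quantile_categories(s[pos], n_categories)
    else:
        cat, cuts = assign_quantile_categories(s, n_categories)

    work = data.copy()
    work["_score_cat"] = pd.Categorical(cat, categories=range(1, n_categories + 1))
    work["_score_cat"] = work["_score_cat"].astype(str)
    cat_spec = ModelSpec(
        spec.outcome, spec.forced_terms, spec.candidate_terms + ("_score_cat",)
    )
    fit = fit_logistic(work, cat_spec)

    y = data[spec.outcome].to_numpy(dtype=int)
    rows = []
    for k in range(1, n_categories + 1):
        in_k = cat == k
        lo = float(s[in_k].min())
        hi = float(s[in_k].max())
        if k == 1:
            orr, ci = 1.0, (1.0, 1.0)
        else:
            col = f"_score_cat[{k}]"
            b = fit.coef(col)
            ci_lo, ci_hi = fit.wald_ci(col)
            orr, ci = float(np.exp(b)), (float(np.exp(ci_lo)), float(np.exp(ci_hi)))
        rows.append({
            "category": k, "range_low": lo, "range_high": hi,
            "n_case": int(y[in_k].sum()), "n_control": int((1 - y[in_k]).sum()),
            "or": orr, "ci_low": ci[0], "ci_high": ci[1],
        })

    work["_score_ord"] = cat.astype(float)
    trend_spec = ModelSpec(
        spec.outcome, spec.forced_terms, spec.candidate_terms + ("_score_ord",)
    )
    trend_fit = fit_logistic(work, trend_spec)
    z = trend_fit.coef("_score_ord") / trend_fit.se("_score_ord")
    trend_p = float(chi2.sf(z * z, 1))
    return CategoryOrTable(pd.DataFrame(rows), trend_p, np.asarray(cuts))


def kfold_cv(
    data: pd.DataFrame,
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
) -> Tuple[np.ndarray, "AucResult"]:
    """Stratified k-fold cross-validated predictions and CV AUC.

    Folds are stratified by case status (shuffled with ``seed``); each
    participant's probability is predicted by the model fitted on the other
    k-1 folds, and the AUC is computed on the pooled out-of-fold
    predictions. ``k == n`` performs deterministic leave-one-out.
    """
    from .metrics import auc as _auc  # local import to avoid cycle

    n = len(data)
    if k < 2:
        raise ModelingError("k must be at least 2")
    if k > n:
        raise ModelingError("k cannot exceed the number of participants")
    y = data[spec.outcome].to_numpy(dtype=int)
    X, _ = build_design(data, spec.terms)
    _check_rank(X)

    if k == n:
        folds = [np.array([i]) for i in range(n)]
    else:
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [test for _, test in skf.split(np.zeros(n), y)]

    oof = np.full(n, np.nan)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        y_tr = y[train]
        if y_tr.sum() == 0 or y_tr.sum() == len(y_tr):
            raise ModelingError(
                "a training fold contains a single outcome class; use fewer, "
                "larger folds"
            )
        X_tr = X.iloc[train]
        # drop indicator columns constant within this training fold
        keep = ["const"] + [
            c for c in X.columns
            if c != "const" and X_tr[c].nunique() > 1
        ]
        res = _fit_glm(y_tr, X_tr[keep], None)
        eta = X.iloc[test][keep].to_numpy(dtype=float) @ np.asarray(res.params)
        oof[test] = expit(eta)
    assert not np.any(np.isnan(oof))
    return oof, _auc(oof, y)
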