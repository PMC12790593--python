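"""Multivariate symptom models and non-nested framework comparison.

Ordinary least squares predicting UPDRS-III totals from band powers, fit
quality via in-sample Pearson r, Gaussian-likelihood information criteria
(AIC = n ln(RSS/n) + 2k with k counting intercept plus slopes, matching the
common OLS-package convention; ranks, not absolute values, are the supported
comparison), the small-sample corrected AICc = AIC + (2k^2 + 2k)/(n - k - 1),
and Davidson-MacKinnon J-tests between non-nested predictor sets.

The three standard frameworks compared: relative total power (single
predictor: relative low beta), absolute total power (theta, low beta, low
gamma), and parameterized power (aperiodic offset, periodic low beta,
periodic low gamma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "RegressionModel",
    "ModelFitMetrics",
    "JTestResult",
    "fit_linear_model",
    "evaluate_model",
    "j_test",
    "compare_frameworks",
    "FRAMEWORK_PREDICTORS",
]

FRAMEWORK_PREDICTORS: dict[str, list[str]] = {
    "relative": ["relative_low_beta"],
    "absolute": ["absolute_theta", "absolute_low_beta", "absolute_low_gamma"],
    "periodic": ["aperiodic_offset", "periodic_low_beta", "periodic_low_gamma"],
}


@dataclass
class RegressionModel:
    predictors: list[str]
    coefficients: np.ndarray  # b0 (intercept) first
    fitted: np.ndarray
    residuals: np.ndarray
    X: np.ndarray  # design matrix including the intercept column
    y: np.ndarray
    coef_se: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def k(self) -> int:
        """Number of estimated mean parameters (intercept + slopes)."""
        return self.X.shape[1]

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)

    def t_pvalues(self) -> np.ndarray:
        dof = self.n - self.k
        t = self.coefficients / self.coef_se
        return 2.0 * scipy.stats.t.sf(np.abs(t), dof)


@dataclass(frozen=True)
class ModelFitMetrics:
    pearson_r: float
    p: float
    aic: float
    bic: float
    aicc: float | None  # None when n <= k + 1
    k: int
    n: int


@dataclass(frozen=True)
class JTestResult:
    """Both directions of a Davidson-MacKinnon J-test.

    p_a_inadequate: significance of B's fitted values added to model A
    (small p = A does not encompass B). And vice versa.
    """

    t_a: float
    p_a_inadequate: float
    t_b: float
    p_b_inadequate: float


def fit_linear_model(X, y, predictors: list[str] | None = None) -> RegressionModel:
    """OLS with intercept; X is (n, p) without the intercept column.

    Accepts a pandas DataFrame (column names become predictor labels) or a
    2-d array. Rank-deficient designs are rejected, naming the collinear
    columns.
    """
    if isinstance(X, pd.DataFrame):
        predictors = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if predictors is None:
        predictors = [f"x{i+1}" for i in range(p)]
    if n <= p:
        raise ValueError(f"need n > number of predictors ({n} observations, {p} predictors)")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cols = [design[:, 0]]
        for j in range(1, design.shape[1]):
            trial = np.column_stack(cols + [design[:, j]])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(predictors[j - 1])
            else:
                cols.append(design[:, j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    dof = n - design.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    cov = sigma2 * np.linalg.inv(design.T @ design)
    return RegressionModel(
        predictors=predictors,
        coefficients=coef,
        fitted=fitted,
        residuals=resid,
        X=design,
        y=y,
        coef_se=np.sqrt(np.diag(cov)),
    )


def evaluate_model(model: RegressionModel) -> ModelFitMetrics:
    """In-sample Pearson r of fit vs observed plus AIC/BIC/AICc."""
    n, k = model.n, model.k
    if np.ptp(model.fitted) == 0:
        r, p = 0.0, 1.0
    else:
        r, p = scipy.stats.pearsonr(model.fitted, model.y)
    rss = model.rss
    if rss <= 0:
        rss = np.finfo(float).tiny  # perfect fit; IC diverge to -inf otherwise
    aic = n * math.log(rss / n) + 2 * k
    bic = n * math.log(rss / n) + k * math.log(n)
    aicc = aic + (2 * k**2 + 2 * k) / (n - k - 1) if n > k + 1 else None
    return ModelFitMetrics(float(r), float(p), float(aic), float(bic), aicc, k, n)


def j_test(model_a: RegressionModel, model_b: RegressionModel) -> JTestResult:
    """Davidson-MacKinnon J-test between two non-nested models of the same y.

    Direction A-vs-B augments A's predictors with B's fitted values and
    t-tests the augmentation coefficient; a small p rejects A as an adequate
    encompassing model. Both directions are returned; the test is asymmetric.
    """
    if model_a.n != model_b.n or not np.allclose(model_a.y, model_b.y):
        raise ValueError("models must be fit to the same response vector")

    def _aug_p(base: RegressionModel, other: RegressionModel) -> tuple[float, float]:
        Xaug = np.column_stack([base.X[:, 1:], other.fitted])
        try:
            m = fit_linear_model(Xaug, base.y)
        except ValueError as err:
            raise ValueError(
                "degenerate comparison: fitted values are collinear with the design"
            ) from err
        t = m.coefficients[-1] / m.coef_se[-1]
        p = 2.0 * scipy.stats.t.sf(abs(t), m.n - m.k)
        return float(t), float(p)

    t_a, p_a = _aug_p(model_a, model_b)
    t_b, p_b = _aug_p(model_b, model_a)
    return JTestResult(t_a, p_a, t_b, p_b)


def compare_frameworks(
    features: pd.DataFrame,
    y_column: str = "updrs_total",
    frameworks: dict[str, list[str]] | None = None,
) -> dict:
    """Fit one model per spectral framework on a matched patient set.

    ``features`` must contain one row per patient with all predictor columns
    and the response; rows with any missing value (e.g. patients excluded by
    the parameterization R^2 filter) are dropped from *every* framework so
    the comparison stays matched. Returns per-framework models and metrics,
    the pairwise J-test matrix, and the information-criterion ranking.
    """
    frameworks = frameworks or FRAMEWORK_PREDICTORS
    needed = sorted({c for cols in frameworks.values() for c in cols} | {y_column})
    missing = [c for c in needed if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    matched = features.dropna(subset=needed)
    excluded = sorted(set(features.index) - set(matched.index))
    y = matched[y_column].to_numpy(dtype=float)

    models, metrics = {}, {}
    for name, cols in frameworks.items():
        models[name] = fit_linear_model(matched[cols], y)
        metrics[name] = evaluate_model(models[name])

    jtests = {}
    names = list(frameworks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            try:
                jtests[(a, b)] = j_test(models[a], models[b])
            except ValueError:
                jtests[(a, b)] = None
    ranking = sorted(
        names,
        key=lambda nm: metrics[nm].aicc if metrics[nm].aicc is not None else metrics[nm].aic,
    )
    return {
        "models": models,
        "metrics": metrics,
        "j_tests": jtests,
        "ranking_by_aicc": ranking,
        "n_matched": len(matched),
        "excluded": excluded,
    }


def model_report(result: dict) -> pd.DataFrame:
    """Tidy per-framework summary table (one row per framework)."""
    rows = []
    for name, m in result["metrics"].items():
        model = result["models"][name]
        rows.append(
            {
                "framework": name,
                "n": m.n,
                "k": m.k,
                "pearson_r": m.pearson_r,
                "p": m.p,
                "aic": m.aic,
                "aicc": m.aicc,
                "bic": m.bic,
                "coefficients": dict(
                    zip(["intercept"] + model.predictors, model.coefficients.round(4))
                ),
            }
        )
    return pd.DataFrame(rows)
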