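"""Multiple linear regression with backward elimination.

First-order ordinary-least-squares models of each culture response in
the four inputs (CE and CF concentration, elicitor adding day, harvest
day).  Backward elimination drops, one at a time, the non-intercept term
with the largest p-value above the significance level (default 0.05)
and refits until every retained term is significant; the intercept is
always kept.  Term importance is ranked by absolute t-statistic: a more
influential input carries a larger |t|.

The OLS fit itself (coefficients, standard errors from the unbiased
residual variance, two-sided p-values on n - k degrees of freedom) is
delegated to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg

from .metrics import FitMetrics, evaluate

INTERCEPT = "intercept"


class SingularDesignError(ValueError):
    """The design matrix is rank-deficient (collinear columns)."""


@dataclass
class RegressionFit:
    """An OLS fit: retained terms with coefficients, SEs, t and p values."""

    terms: list[str]  # intercept first, then retained inputs
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    alpha: float | None = None
    removal_order: list[str] = field(default_factory=list)
    metrics_train: FitMetrics | None = None
    metrics_test: FitMetrics | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        kept = [t for t in self.terms if t != INTERCEPT]
        coef = dict(zip(self.terms, self.coefficients))
        out = np.full(len(X), coef.get(INTERCEPT, 0.0))
        for term in kept:
            out = out + coef[term] * np.asarray(X[term], float)
        return out

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "t_values": self.t_values.tolist(),
            "p_values": self.p_values.tolist(),
            "alpha": self.alpha,
            "removal_order": self.removal_order,
            "metrics_train": self.metrics_train.to_dict() if self.metrics_train else None,
            "metrics_test": self.metrics_test.to_dict() if self.metrics_test else None,
        }


def t_statistic(coefficient: float, standard_error: float) -> float:
    """t = coefficient / standard error."""
    if standard_error <= 0:
        raise ValueError("standard error must be positive")
    return coefficient / standard_error


def _as_frame(X, term_names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.reset_index(drop=True)
    X = np.asarray(X, float)
    names = term_names or [f"x{i + 1}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=names)


def _check_rank(Xf: pd.DataFrame) -> None:
    design = np.column_stack([np.ones(len(Xf)), Xf.to_numpy(float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # QR with column pivoting: pivots beyond the numerical rank point
        # at the columns that add no new direction.
        _, _, piv = linalg.qr(design, pivoting=True)
        names = [INTERCEPT] + list(Xf.columns)
        culprits = [names[j] for j in piv[rank:]]
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear columns: {culprits}"
        )


def fit_mlr(X, y, term_names: list[str] | None = None) -> RegressionFit:
    """Ordinary least squares of y on the given inputs plus an intercept."""
    Xf = _as_frame(X, term_names)
    yv = np.asarray(y, float).ravel()
    if len(Xf) != yv.size:
        raise ValueError("X and y lengths differ")
    if yv.size <= Xf.shape[1] + 1:
        raise ValueError("need more observations than model terms")
    _check_rank(Xf)
    design = sm.add_constant(Xf.to_numpy(float), has_constant="add")
    res = sm.OLS(yv, design).fit()
    terms = [INTERCEPT] + list(Xf.columns)
    fit = RegressionFit(
        terms=terms,
        coefficients=np.asarray(res.params, float),
        standard_errors=np.asarray(res.bse, float),
        t_values=np.asarray(res.tvalues, float),
        p_values=np.asarray(res.pvalues, float),
    )
    fit.metrics_train = evaluate(yv, fit.predict(Xf))
    return fit


def backward_eliminate(X, y, alpha: float = 0.05,
                       term_names: list[str] | None = None) -> RegressionFit:
    """Backward elimination at significance level ``alpha``.

    Repeatedly removes the non-intercept term with the largest p-value
    exceeding alpha and refits, until all retained terms have p <= alpha.
    The intercept is exempt even when non-significant.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    Xf = _as_frame(X, term_names)
    removed: list[str] = []
    while True:
        fit = fit_mlr(Xf, y)
        candidates = [
            (p, name)
            for name, p in zip(fit.terms, fit.p_values)
            if name != INTERCEPT and p > alpha
        ]
        if not candidates or Xf.shape[1] == 0:
            fit.alpha = alpha
            fit.removal_order = removed
            return fit
        worst = max(candidates)[1]
        removed.append(worst)
        Xf = Xf.drop(columns=[worst])
        if Xf.shape[1] == 0:
            fit = _intercept_only(y)
            fit.alpha = alpha
            fit.removal_order = removed
            return fit


def _intercept_only(y) -> RegressionFit:
    yv = np.asarray(y, float).ravel()
    n = yv.size
    mean = float(yv.mean())
    se = float(yv.std(ddof=1) / np.sqrt(n))
    from scipy import stats

    t = mean / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    fit = RegressionFit(
        terms=[INTERCEPT],
        coefficients=np.array([mean]),
        standard_errors=np.array([se]),
        t_values=np.array([t]),
        p_values=np.array([p]),
    )
    fit.metrics_train = None  # r2 undefined for the null model on itself
    return fit


def rank_terms_by_t(fit: RegressionFit) -> list[str]:
    """Non-intercept terms sorted by decreasing |t|; ties keep the
    original column order (stable sort)."""
    pairs = [
        (name, abs(t))
        for name, t in zip(fit.terms, fit.t_values)
        if name != INTERCEPT
    ]
    return [name for name, _ in sorted(pairs, key=lambda p: -p[1])]
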