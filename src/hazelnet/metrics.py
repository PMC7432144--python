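"""Goodness-of-fit statistics used throughout the package.

Three statistics summarise model accuracy on a data subset: the
coefficient of determination R², the root mean square error (RMSE, in
response units) and the mean absolute percentage error (MAPE, percent):

    MAPE = (1/n) * sum(|(y_act - y_est) / y_act|) * 100

R² is computed as 1 - SS_res/SS_tot about the mean of the actual values,
so it may be negative for models worse than the mean predictor; this is
the strict definition, not squared Pearson correlation (the two differ
off the training set).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass(frozen=True)
class FitMetrics:
    """R², RMSE and MAPE for one model on one data subset."""

    r2: float
    rmse: float
    mape: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _paired_vectors(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.shape != p.shape:
        raise ValueError(
            f"actual and predicted lengths differ: {a.size} vs {p.size}"
        )
    if a.size == 0:
        raise ValueError("empty vectors")
    return a, p


def mape(actual, predicted) -> float:
    """Mean absolute percentage error, in percent.

    Undefined when any actual value is zero (relative error divides by
    the actual value).
    """
    a, p = _paired_vectors(actual, predicted)
    if np.any(a == 0):
        raise ValueError("MAPE is undefined when an actual value equals 0")
    return float(np.mean(np.abs((a - p) / a)) * 100.0)


def rmse(actual, predicted) -> float:
    """Root mean square error, in response units."""
    a, p = _paired_vectors(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def r2(actual, predicted) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot."""
    a, p = _paired_vectors(actual, predicted)
    if a.size < 2:
        raise ValueError("r2 requires at least 2 observations")
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r2 is undefined for a constant actual vector")
    ss_res = float(np.sum((a - p) ** 2))
    return 1.0 - ss_res / ss_tot


def evaluate(actual, predicted) -> FitMetrics:
    """All three statistics for one (actual, predicted) pair.

    MAPE is computed over the rows whose actual value is non-zero (a
    zero observation has no defined relative error); it is NaN when no
    such row exists.  The strict single-statistic :func:`mape` raises
    instead.
    """
    a, p = _paired_vectors(actual, predicted)
    nz = a != 0
    mape_val = mape(a[nz], p[nz]) if nz.any() else float("nan")
    return FitMetrics(r2=r2(a, p), rmse=rmse(a, p), mape=mape_val, n=a.size)
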