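"""Variable sensitivity analysis of fitted perceptron surrogates.

For each input, the variable sensitivity error (VSE) is the model RMSE
when that input is made unavailable; the variable sensitivity ratio
(VSR) is VSE divided by the base RMSE with all inputs available.  Raw
ratios are rescaled to [0, 1] by anchoring "no effect" (ratio <= 1) at
zero and the most influential input at one:

    vsr_scaled_i = max(vsr_raw_i - 1, 0) / max_j max(vsr_raw_j - 1, 0)

which preserves the ranking (any strictly monotone transform does).
"Unavailable" is implemented as mean-substitution of the column over
the evaluation rows — deterministic and convention-standard; random
column permutation is provided as an alternative perturbation used as a
cross-check oracle.  Sensitivity is evaluated on all data lines
(training and testing subsets together).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import rmse
from .neuralnet import MLPModel, forward


class DegenerateModelError(ValueError):
    """Base RMSE is zero; sensitivity ratios are undefined."""


def vse(model: MLPModel, X, y, input_index: int, method: str = "mean",
        rng=None) -> float:
    """Model RMSE with one input column made unavailable.

    ``method="mean"`` replaces the column by its mean over the
    evaluation rows; ``method="permute"`` shuffles it (requires
    ``rng``).
    """
    X = np.atleast_2d(np.asarray(X, float))
    yv = np.asarray(y, float).ravel()
    if not 0 <= input_index < X.shape[1]:
        raise IndexError(f"input_index {input_index} out of range")
    Xp = X.copy()
    if method == "mean":
        Xp[:, input_index] = Xp[:, input_index].mean()
    elif method == "permute":
        if rng is None:
            rng = np.random.default_rng(0)
        Xp[:, input_index] = rng.permutation(Xp[:, input_index])
    else:
        raise ValueError(f"unknown perturbation method {method!r}")
    return rmse(yv, forward(model, Xp))


@dataclass
class SensitivityReport:
    """Per-input VSE/VSR importance of a fitted surrogate."""

    input_names: list[str]
    base_rmse: float
    vse: np.ndarray
    vsr_raw: np.ndarray
    vsr_scaled: np.ndarray
    rank: np.ndarray  # 1 = most important
    n_rows: int
    subset: str = "all"

    def ranked_inputs(self) -> list[str]:
        order = np.argsort(self.rank, kind="stable")
        return [self.input_names[i] for i in order]

    def to_dict(self) -> dict:
        return {
            "input_names": self.input_names,
            "base_rmse": self.base_rmse,
            "vse": self.vse.tolist(),
            "vsr_raw": self.vsr_raw.tolist(),
            "vsr_scaled": self.vsr_scaled.tolist(),
            "rank": self.rank.tolist(),
            "n_rows": self.n_rows,
            "subset": self.subset,
        }

    def to_text(self) -> str:
        lines = [
            f"{'input':<14}{'VSE':>10}{'VSR':>10}{'scaled':>10}{'rank':>6}",
        ]
        for i, name in enumerate(self.input_names):
            lines.append(
                f"{name:<14}{self.vse[i]:>10.4f}{self.vsr_raw[i]:>10.4f}"
                f"{self.vsr_scaled[i]:>10.3f}{self.rank[i]:>6d}"
            )
        lines.append(f"base RMSE {self.base_rmse:.4f} on {self.n_rows} rows")
        return "\n".join(lines)


def vsr_report(model: MLPModel, X, y, method: str = "mean",
               rng=None, subset: str = "all") -> SensitivityReport:
    """VSE, raw and rescaled VSR, and importance rank for every input."""
    X = np.atleast_2d(np.asarray(X, float))
    yv = np.asarray(y, float).ravel()
    base = rmse(yv, forward(model, X))
    if base == 0.0:
        raise DegenerateModelError("base RMSE is 0; VSR undefined")
    errors = np.array([
        vse(model, X, yv, j, method=method, rng=rng) for j in range(X.shape[1])
    ])
    raw = errors / base
    excess = np.maximum(raw - 1.0, 0.0)
    top = excess.max()
    scaled = excess / top if top > 0 else np.zeros_like(excess)
    # rank 1 = largest scaled VSR; ties resolved by input order
    order = np.argsort(-scaled, kind="stable")
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(1, len(order) + 1)
    return SensitivityReport(
        input_names=list(model.input_names),
        base_rmse=base,
        vse=errors,
        vsr_raw=raw,
        vsr_scaled=scaled,
        rank=rank,
        n_rows=X.shape[0],
        subset=subset,
    )
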