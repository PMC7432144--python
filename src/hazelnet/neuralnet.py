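"""Three-layer feed-forward perceptron trained by back-propagation.

One hidden layer of hyperbolic-tangent ("tansig") units and a single
linear ("purelin") output, the classic architecture for small
bioprocess surrogate models.  Inputs and target are min-max scaled to
[-1, 1] on the training ranges (the scaler is part of the model, so a
saved model is self-contained).  Training is full-batch gradient
descent with momentum and an adaptive learning rate (the step is
rejected and the rate reduced when the error ratio exceeds a threshold,
and gently increased otherwise), with early stopping on an internal
validation fraction of the training rows.  Everything is deterministic
for a given seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .metrics import FitMetrics, evaluate

N_INPUTS = 4


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """Back-propagation hyperparameters.

    learning_rate is the initial step size on the scaled mean-squared
    error; it adapts during training (x ``lr_up`` after an accepted
    step, x ``lr_down`` after a rejected one).  ``patience`` is the
    number of epochs without validation improvement before stopping.
    """

    learning_rate: float = 0.05
    momentum: float = 0.9
    max_epochs: int = 4000
    patience: int = 400
    val_fraction: float = 0.15
    lr_up: float = 1.05
    lr_down: float = 0.7
    max_error_ratio: float = 1.04


@dataclass
class MLPModel:
    """Weights, scalers and provenance of one fitted single-output MLP."""

    hidden_weights: np.ndarray  # (n_hidden, 4)
    hidden_biases: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (n_hidden,)
    output_bias: float
    input_min: np.ndarray  # (4,)
    input_max: np.ndarray  # (4,)
    target_min: float
    target_max: float
    input_names: list[str] = field(
        default_factory=lambda: ["ce_conc", "cf_conc", "adding_day", "harvest_day"]
    )
    hidden_activation: str = "tansig"
    output_activation: str = "purelin"
    training_meta: dict = field(default_factory=dict)

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    def validate(self) -> None:
        h = self.n_hidden
        if h < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.hidden_weights.shape != (h, N_INPUTS):
            raise ValueError("hidden_weights shape mismatch")
        if self.hidden_biases.shape != (h,) or self.output_weights.shape != (h,):
            raise ValueError("hidden/output vector length mismatch")
        for arr in (self.hidden_weights, self.hidden_biases, self.output_weights):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite weights")
        if np.any(self.input_min >= self.input_max) or self.target_min >= self.target_max:
            raise ValueError("scaler requires min < max")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("hidden_weights", "hidden_biases", "output_weights",
                    "input_min", "input_max"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        model = cls(
            hidden_weights=np.asarray(d["hidden_weights"], float),
            hidden_biases=np.asarray(d["hidden_biases"], float),
            output_weights=np.asarray(d["output_weights"], float),
            output_bias=float(d["output_bias"]),
            input_min=np.asarray(d["input_min"], float),
            input_max=np.asarray(d["input_max"], float),
            target_min=float(d["target_min"]),
            target_max=float(d["target_max"]),
            input_names=list(d.get("input_names", [])) or None
            or ["ce_conc", "cf_conc", "adding_day", "harvest_day"],
            hidden_activation=d.get("hidden_activation", "tansig"),
            output_activation=d.get("output_activation", "purelin"),
            training_meta=dict(d.get("training_meta", {})),
        )
        model.validate()
        return model


def scale_inputs(model: MLPModel, X: np.ndarray) -> np.ndarray:
    span = model.input_max - model.input_min
    return 2.0 * (X - model.input_min) / span - 1.0


def unscale_target(model: MLPModel, ys: np.ndarray) -> np.ndarray:
    return model.target_min + (ys + 1.0) * (model.target_max - model.target_min) / 2.0


def forward(model: MLPModel, X) -> np.ndarray:
    """Predict responses for a matrix of (ce, cf, adding day, harvest day).

    Inputs well outside the training range trigger an extrapolation
    warning (10 % of the range beyond each bound) but are still
    evaluated.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != N_INPUTS:
        raise ValueError(f"expected {N_INPUTS} input columns, got {X.shape[1]}")
    span = model.input_max - model.input_min
    lo = model.input_min - 0.1 * span
    hi = model.input_max + 0.1 * span
    if np.any(X < lo) or np.any(X > hi):
        warnings.warn(
            "inputs outside the training range; prediction is extrapolation",
            stacklevel=2,
        )
    Xs = scale_inputs(model, X)
    hidden = np.tanh(Xs @ model.hidden_weights.T + model.hidden_biases)
    ys = hidden @ model.output_weights + model.output_bias
    return unscale_target(model, ys)


def _loss_and_grads(W, b, v, c, Xs, ys):
    """Mean-squared error on scaled targets and its analytic gradients."""
    n = Xs.shape[0]
    hidden = np.tanh(Xs @ W.T + b)
    pred = hidden @ v + c
    err = pred - ys
    loss = float(np.mean(err**2))
    dpred = 2.0 * err / n
    dv = hidden.T @ dpred
    dc = float(np.sum(dpred))
    dhidden = np.outer(dpred, v) * (1.0 - hidden**2)
    dW = dhidden.T @ Xs
    db = dhidden.sum(axis=0)
    return loss, dW, db, dv, dc


def train(X, y, n_hidden: int, config: TrainConfig | None = None,
          seed: int = 0) -> MLPModel:
    """Fit a single-output MLP by full-batch back-propagation.

    Weights start uniform in [-0.5, 0.5].  A validation slice
    (``config.val_fraction`` of the rows, drawn from the seed) drives
    early stopping; the weights achieving the best validation error are
    returned.  Raises :class:`TrainingDivergedError` when the loss
    becomes non-finite.
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, float))
    yv = np.asarray(y, float).ravel()
    if X.shape[0] != yv.size:
        raise ValueError("X and y lengths differ")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 observations to train")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")

    input_min, input_max = X.min(axis=0), X.max(axis=0)
    span = input_max - input_min
    if np.any(span <= 0):
        raise ValueError("constant input column; cannot scale to [-1, 1]")
    tmin, tmax = float(yv.min()), float(yv.max())
    if tmax <= tmin:
        raise ValueError("constant target; nothing to fit")
    Xs = 2.0 * (X - input_min) / span - 1.0
    ys = 2.0 * (yv - tmin) / (tmax - tmin) - 1.0

    rng = np.random.default_rng(seed)
    n = Xs.shape[0]
    n_val = int(round(config.val_fraction * n))
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    if fit_idx.size == 0:
        raise ValueError("validation fraction leaves no training rows")
    Xf, yf = Xs[fit_idx], ys[fit_idx]
    Xv, yvl = Xs[val_idx], ys[val_idx]

    W = rng.uniform(-0.5, 0.5, (n_hidden, N_INPUTS))
    b = rng.uniform(-0.5, 0.5, n_hidden)
    v = rng.uniform(-0.5, 0.5, n_hidden)
    c = float(rng.uniform(-0.5, 0.5))

    vel = [np.zeros_like(W), np.zeros_like(b), np.zeros_like(v), 0.0]
    lr = config.learning_rate
    loss, dW, db, dv, dc = _loss_and_grads(W, b, v, c, Xf, yf)

    def val_error(W, b, v, c):
        if Xv.shape[0] == 0:
            return loss
        hidden = np.tanh(Xv @ W.T + b)
        return float(np.mean((hidden @ v + c - yvl) ** 2))

    best = (W.copy(), b.copy(), v.copy(), c)
    best_val = val_error(W, b, v, c)
    stall = 0
    epochs_run = 0

    for epoch in range(config.max_epochs):
        epochs_run = epoch + 1
        vel[0] = config.momentum * vel[0] - lr * dW
        vel[1] = config.momentum * vel[1] - lr * db
        vel[2] = config.momentum * vel[2] - lr * dv
        vel[3] = config.momentum * vel[3] - lr * dc
        Wn, bn = W + vel[0], b + vel[1]
        vn, cn = v + vel[2], c + vel[3]
        new_loss, ndW, ndb, ndv, ndc = _loss_and_grads(Wn, bn, vn, cn, Xf, yf)
        if not np.isfinite(new_loss):
            raise TrainingDivergedError(
                "training error became non-finite; try a smaller learning rate"
            )
        if new_loss > loss * config.max_error_ratio:
            # reject the step: shrink the rate, kill the momentum
            lr *= config.lr_down
            vel = [np.zeros_like(W), np.zeros_like(b), np.zeros_like(v), 0.0]
            if lr < 1e-12:
                break
            continue
        W, b, v, c = Wn, bn, vn, cn
        loss, dW, db, dv, dc = new_loss, ndW, ndb, ndv, ndc
        lr *= config.lr_up
        ve = val_error(W, b, v, c)
        if ve < best_val - 1e-12:
            best_val = ve
            best = (W.copy(), b.copy(), v.copy(), c)
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    W, b, v, c = best
    model = MLPModel(
        hidden_weights=W,
        hidden_biases=b,
        output_weights=v,
        output_bias=float(c),
        input_min=input_min,
        input_max=input_max,
        target_min=tmin,
        target_max=tmax,
        training_meta={
            "seed": int(seed),
            "n_hidden": int(n_hidden),
            "epochs_run": int(epochs_run),
            "learning_rate": config.learning_rate,
            "momentum": config.momentum,
            "val_fraction": config.val_fraction,
            "patience": config.patience,
            "best_val_mse_scaled": best_val,
            "n_train_rows": int(n),
        },
    )
    model.validate()
    return model


def evaluate_model(model: MLPModel, X, y) -> FitMetrics:
    """R²/RMSE/MAPE of the model on a data subset."""
    return evaluate(np.asarray(y, float).ravel(), forward(model, X))
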